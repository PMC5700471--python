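# Connector phrases joining a head noun to its body-part tail.
of
of the
in the
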