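# Candidates containing one of these phrases anywhere are removed.
was found
were found
in this study
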