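# Nouns denoting normal (non-pathological) concepts; a two-token candidate
# containing one of these cannot name an abnormality on its own.
development
function
growth
structure
metabolism
ability
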