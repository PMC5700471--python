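# Candidates whose whole surface equals one of these phrases are removed;
# the same word inside a longer candidate ("enlarged hippocampus") survives.
hippocampus
neuroanatomy
patient
patients
syndrome
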