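name	sequence	orientation
gliadin_F	ATGAARACMTTTCYCATC	forward
gliadin_R	YAGTTRGTACCRAAGATGM	reverse
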