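"""Physical constants used throughout the package."""

#: Proton gyromagnetic ratio in rad/s/T.
GAMMA = 2.6752218744e8
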