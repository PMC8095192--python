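"""D65 efficacy-of-luminous-radiation constants [mW/lm].

Generated by scripts/freeze_d65_constants.py from the vendored D65 and
action-spectrum tables; frozen at 15 significant digits so downstream
EDI/EDL outputs are bit-for-bit reproducible across platforms.
"""

D65_ELR = {
    "sc": 1.26348410201633,
    "mc": 1.75737575133512,
    "lc": 1.80612821390662,
    "rh": 1.45253137231315,
    "mel": 1.5763320938813,
}
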