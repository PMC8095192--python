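"""Regenerate spdcalc/_d65_constants.py from the vendored tables.

Run from the repository root after any change to the D65 construction or
the action-spectrum tables:

    python scripts/freeze_d65_constants.py
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from spdcalc.alpha_opic import compute_d65_elr  # noqa: E402

HEADER = '''"""D65 efficacy-of-luminous-radiation constants [mW/lm].

Generated by scripts/freeze_d65_constants.py from the vendored D65 and
action-spectrum tables; frozen at 15 significant digits so downstream
EDI/EDL outputs are bit-for-bit reproducible across platforms.
"""

D65_ELR = {
'''


def main() -> None:
    constants = compute_d65_elr()
    out = HEADER
    for ch, value in constants.items():
        out += f'    "{ch}": {value:.15g},\n'
    out += "}\n"
    target = (pathlib.Path(__file__).resolve().parents[1]
              / "src" / "spdcalc" / "_d65_constants.py")
    target.write_text(out)
    print(f"wrote {target}")
    for ch, value in constants.items():
        print(f"  {ch}: {value:.15g} mW/lm")


if __name__ == "__main__":
    main()
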