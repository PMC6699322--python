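"""Integer label codes for the tissue classes used across the package."""

BACKGROUND = 0
NORMAL = 1
CYST = 2
TUMOR_CENTRAL = 3
TUMOR_PERIPHERAL = 4
OTHER = 5

CODES = {
    "background": BACKGROUND,
    "normal": NORMAL,
    "cyst": CYST,
    "tumor_central": TUMOR_CENTRAL,
    "tumor_peripheral": TUMOR_PERIPHERAL,
    "other": OTHER,
}

NAMES = {code: name for name, code in CODES.items()}
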