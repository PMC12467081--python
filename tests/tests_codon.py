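"""A hard-coded standard codon table, independent of the package's
translation path, shared by classification and generator tests."""

CODON_TABLE = {}
_bases = "TCAG"
_aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _a in enumerate(_bases):
    for _j, _b in enumerate(_bases):
        for _k, _c in enumerate(_bases):
            CODON_TABLE[_a + _b + _c] = _aas[16 * _i + 4 * _j + _k]


def translate_oracle(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds) - 2, 3))
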