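"""Ion channel constants and annotations for py-MBMS spectra of woody biomass.

Spectra are recorded over integer m/z channels 30-450 (421 channels).  Lignin
content is estimated from a fixed set of 17 lignin-diagnostic ions; the
syringyl/guaiacyl (S/G) monomer ratio from the subsets of those ions known to
derive from sinapyl (S) vs coniferyl (G) units.
"""

from __future__ import annotations

MZ_MIN = 30
MZ_MAX = 450

#: All integer m/z channels carried by a spectrum.
ALL_CHANNELS = tuple(range(MZ_MIN, MZ_MAX + 1))

#: Ions summed for the relative lignin content index.
LIGNIN_IONS = frozenset(
    {120, 124, 137, 138, 150, 152, 154, 164, 167, 168, 178, 180, 181, 182, 194, 208, 210}
)

#: Syringyl (sinapyl-monomer derived) ions.
S_IONS = frozenset({154, 167, 168, 182, 194, 208, 210})

#: Guaiacyl (coniferyl-monomer derived) ions.
G_IONS = frozenset({124, 137, 138, 150, 164, 178})

assert S_IONS <= LIGNIN_IONS and G_IONS <= LIGNIN_IONS and not (S_IONS & G_IONS)

#: Compact source annotation for commonly discussed ions (C = carbohydrate,
#: L = lignin, P = phenolics, S = S-lignin, G = G-lignin, A = acetyl).
ION_SOURCES: dict[int, str] = {
    57: "C",
    60: "A/C",
    66: "P/L",
    73: "C",
    85: "C5",
    94: "P/L",
    97: "C",
    98: "C6",
    109: "P/L",
    114: "C5",
    120: "H-lignin/coumarate",
    121: "P/L",
    124: "G",
    126: "C6",
    135: "G",
    137: "G",
    138: "P/G",
    150: "G/H/ferulate",
    151: "G",
    152: "G",
    154: "S",
    164: "G",
    167: "S",
    168: "S",
    178: "G",
    180: "L",
    181: "S",
    182: "S",
    193: "S-fragment",
    194: "S",
    208: "S",
    210: "S",
    272: "G-G dimer",
    286: "lignin dimer",
    302: "S-G dimer",
}


def validate_channels(channels) -> list[int]:
    """Return sorted integer channels, rejecting anything outside 30-450."""
    out = sorted(int(c) for c in channels)
    bad = [c for c in out if c < MZ_MIN or c > MZ_MAX]
    if bad:
        raise ValueError(f"m/z channels outside [{MZ_MIN}, {MZ_MAX}]: {bad[:5]}")
    return out
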