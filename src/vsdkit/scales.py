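"""Bundled per-residue property scales for propensity correlations.

Each scale maps one-letter amino-acid codes to a published value and carries
its citation. ``get_scale`` accepts either a bundled name or any user-supplied
mapping, so correlations can be run against other scales (e.g. a
membrane-derived helical-propensity scale) without code changes.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PropertyScale:
    name: str
    values: dict
    citation: str
    direction: str = ""   # what a high value means

    def __getitem__(self, aa):
        return self.values[aa.upper()]


KYTE_DOOLITTLE = PropertyScale(
    name="kyte_doolittle",
    citation="Kyte & Doolittle, J Mol Biol 157:105-132 (1982)",
    direction="higher = more hydrophobic",
    values={
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
        "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
        "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
        "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    },
)

# Helix propensity as the free-energy cost of helix formation relative to Ala;
# lower = stronger helix former.
PACE_SCHOLTZ_HELIX = PropertyScale(
    name="helix_propensity",
    citation="Pace & Scholtz, Biophys J 75:422-427 (1998)",
    direction="higher = weaker helix former (kcal/mol vs Ala)",
    values={
        "A": 0.0, "L": 0.21, "R": 0.21, "M": 0.24, "K": 0.26,
        "Q": 0.39, "E": 0.40, "I": 0.41, "W": 0.49, "S": 0.50,
        "Y": 0.53, "F": 0.54, "H": 0.61, "V": 0.61, "N": 0.65,
        "T": 0.66, "C": 0.68, "D": 0.69, "G": 1.0, "P": 3.16,
    },
)

CHOU_FASMAN_TURN = PropertyScale(
    name="turn_propensity",
    citation="Chou & Fasman, Annu Rev Biochem 47:251-276 (1978)",
    direction="higher = stronger beta-turn former",
    values={
        "N": 1.56, "G": 1.56, "P": 1.52, "D": 1.46, "S": 1.43,
        "C": 1.19, "Y": 1.14, "K": 1.01, "Q": 0.98, "T": 0.96,
        "W": 0.96, "R": 0.95, "H": 0.95, "E": 0.74, "A": 0.66,
        "M": 0.60, "F": 0.60, "L": 0.59, "V": 0.50, "I": 0.47,
    },
)

BUNDLED_SCALES = {s.name: s for s in
                  (KYTE_DOOLITTLE, PACE_SCHOLTZ_HELIX, CHOU_FASMAN_TURN)}


def get_scale(scale) -> PropertyScale:
    """Resolve a scale name or mapping to a PropertyScale."""
    if isinstance(scale, PropertyScale):
        return scale
    if isinstance(scale, str):
        try:
            return BUNDLED_SCALES[scale]
        except KeyError:
            raise KeyError(f"unknown scale '{scale}'; bundled: "
                           f"{sorted(BUNDLED_SCALES)}")
    return PropertyScale(name="custom", values=dict(scale), citation="user-supplied")
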