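"""Shared constants: the amino-acid alphabet and background frequency tables.

Every matrix in the package uses the canonical alphabetical one-letter
ordering ``ACDEFGHIKLMNPQRSTVWY`` for its amino-acid axis.
"""

from __future__ import annotations

import numpy as np

#: Canonical amino-acid column order used by every matrix in the package.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Length of the MHC binding core.
CORE_LENGTH: int = 9

#: Sentinel cluster name for peptides rejected by every allele.
TRASH: str = "TRASH"

#: Label used by the synthetic generator for injected contaminant peptides.
CONTAMINANT: str = "CONTAMINANT"

# Robinson & Robinson amino-acid frequencies in natural proteins,
# re-normalised to sum to exactly 1 in the canonical column order.
_RR = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

#: Natural-protein background frequencies (20-vector, canonical order).
NATURAL_BACKGROUND: np.ndarray = np.array([_RR[a] for a in AMINO_ACIDS])
NATURAL_BACKGROUND = NATURAL_BACKGROUND / NATURAL_BACKGROUND.sum()
NATURAL_BACKGROUND.setflags(write=False)

#: Uniform 1/20 background.
UNIFORM_BACKGROUND: np.ndarray = np.full(20, 1.0 / 20.0)
UNIFORM_BACKGROUND.setflags(write=False)


def encode_peptide(peptide: str) -> np.ndarray:
    """Map a peptide to integer indices into :data:`AMINO_ACIDS`.

    Raises ``ValueError`` on any non-canonical residue.
    """
    try:
        return np.array([AA_INDEX[a] for a in peptide], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(
            f"peptide {peptide!r} contains non-canonical residue {exc.args[0]!r}"
        ) from None


def is_canonical(peptide: str) -> bool:
    """True if every residue is one of the 20 canonical one-letter codes."""
    return bool(peptide) and all(a in AA_INDEX for a in peptide)
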