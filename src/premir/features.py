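"""The 46-dimensional sequence/structure feature vector.

Fourteen scalar features summarise thermodynamics and hairpin anatomy;
the remaining 32 are normalised frequencies of left-triplet
sequence-structure codes counted over the stem region.  The order is
frozen in :data:`FEATURE_NAMES`; trained models record a fingerprint of
it and refuse mismatched vectors.

Scalar conventions (LS = window length, GC as counts or percent as noted):

* N(MFE)   = -MFE/1000
* N(MFEI)  = MFEI/10 with MFEI = (-100*MFE/LS)/GC%
* N(AMFE)  = (-MFE/LS)*10
* N(NNB)   = pairs/1000, N(ANNB) = pairs/LS, N(NNS) = pairs/stem_nt
* N(GC)    = (#G + #C)/1000
* N(Diversity) = ensemble diversity/LS, N(Freq/100) = P(MFE structure),
  N(dD) = ensemble-MFE bp distance/LS
* N(D_interlp/1000) = mean inter-loop distance/1000 (0 when < 2 loops)
* N(|A-U|/LS), N(l_rsym_rgn/100), N(l_sym_rgn/100)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fold import HairpinAnatomy, SecondaryStructure, _pair_table

__all__ = [
    "FEATURE_NAMES",
    "TRIPLET_CODES",
    "FeatureVector",
    "FeatureError",
    "mfe_features",
    "pairing_features",
    "structural_features",
    "triplet_features",
    "encode",
    "gc_percent",
]

# the 8 three-position pairing patterns, ')' collapsed onto '('
_PATTERNS = ("(((", "((.", "(.(", "(..", ".((", ".(.", "..(", "...")
TRIPLET_CODES: tuple[str, ...] = tuple(
    f"{nt}{pat}" for nt in "ACGU" for pat in _PATTERNS
)

SCALAR_NAMES: tuple[str, ...] = (
    "N(MFE)",
    "N(MFEI)",
    "N(AMFE)",
    "N(NNB)",
    "N(ANNB)",
    "N(NNS)",
    "N(GC)",
    "N(Diversity)",
    "N(Freq/100)",
    "N(dD)",
    "N(D_interlp/1000)",
    "N(|A-U|/LS)",
    "N(l_rsym_rgn/100)",
    "N(l_sym_rgn/100)",
)

FEATURE_NAMES: tuple[str, ...] = SCALAR_NAMES + TRIPLET_CODES
assert len(FEATURE_NAMES) == 46


class FeatureError(ValueError):
    """A feature could not be computed from the given inputs."""


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 46-dimensional classifier input."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.names),):
            raise ValueError(
                f"expected {len(self.names)} features, got {self.values.shape}"
            )

    def __len__(self) -> int:
        return len(self.values)


def gc_percent(seq: str) -> float:
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def mfe_features(mfe: float, ls: int, gc_pct: float) -> tuple[float, float, float]:
    """(N(MFE), N(MFEI), N(AMFE)) from the folding energy."""
    if ls <= 0:
        raise FeatureError("sequence length must be positive")
    if gc_pct <= 0:
        raise FeatureError("MFEI undefined for GC content of 0")
    mfei = (-100.0 * mfe / ls) / gc_pct
    return (-mfe / 1000.0, mfei / 10.0, (-mfe / ls) * 10.0)


def pairing_features(anatomy: HairpinAnatomy, seq: str) -> tuple[float, float, float, float]:
    """(N(NNB), N(ANNB), N(NNS), N(GC))."""
    ls = len(seq)
    nnb = anatomy.n_base_pairs
    nns = anatomy.stem_region_nt
    s = seq.upper()
    ngc = (s.count("G") + s.count("C")) / 1000.0
    return (nnb / 1000.0, nnb / ls, (nnb / nns) if nns else 0.0, ngc)


def structural_features(
    structure: SecondaryStructure, anatomy: HairpinAnatomy, seq: str
) -> tuple[float, ...]:
    """The seven ensemble/anatomy scalars (features 8-14)."""
    for attr in ("mfe_freq", "diversity", "mean_bp_distance"):
        if getattr(structure, attr) is None:
            raise FeatureError(f"structure is missing ensemble quantity {attr!r}")
    ls = len(seq)
    s = seq.upper().replace("T", "U")
    d_interlp = (
        float(np.mean(anatomy.interloop_distances)) if anatomy.interloop_distances else 0.0
    )
    return (
        structure.diversity / ls,
        structure.mfe_freq,
        structure.mean_bp_distance / ls,
        d_interlp / 1000.0,
        abs(s.count("A") - s.count("U")) / ls,
        anatomy.l_rsym_rgn / 100.0,
        anatomy.l_sym_rgn / 100.0,
    )


def _stem_segments(dotbracket: str) -> list[tuple[int, int]]:
    """Maximal [start, end) runs belonging to the stem region: everything
    between the outermost and innermost pairs, i.e. the structure minus
    external single-stranded tails and hairpin (terminal) loops."""
    partner = _pair_table(dotbracket)
    n = len(dotbracket)
    keep = [False] * n
    # depth of enclosing pairs per position
    depth = 0
    depths = [0] * n
    for i, c in enumerate(dotbracket):
        if c == "(":
            depths[i] = depth + 1
            depth += 1
        elif c == ")":
            depths[i] = depth
            depth -= 1
        else:
            depths[i] = depth
    for i in range(n):
        if partner[i] >= 0:
            keep[i] = True
        elif depths[i] > 0:
            keep[i] = True
    # drop hairpin loops: unpaired run whose flanking brackets pair together
    i = 0
    while i < n:
        if dotbracket[i] == "." and keep[i]:
            j = i
            while j < n and dotbracket[j] == ".":
                j += 1
            if i > 0 and j < n and partner[i - 1] == j:
                for k in range(i, j):
                    keep[k] = False
            i = j
        else:
            i += 1
    segments = []
    i = 0
    while i < n:
        if keep[i]:
            j = i
            while j < n and keep[j]:
                j += 1
            segments.append((i, j))
            i = j
        else:
            i += 1
    return segments


def triplet_features(seq: str, dotbracket: str) -> np.ndarray:
    """Normalised frequencies of the 32 left-triplet codes.

    A code is (left nucleotide, pairing pattern of 3 adjacent positions)
    with ')' mapped to '(' — the coding does not distinguish 5' from 3'
    arms.  Windows slide within each contiguous stem-region segment (arm),
    never crossing the terminal loop or external tails; interior loops and
    bulges within an arm are included.  Returns an all-zero vector when no
    width-3 window fits (degenerate stem).
    """
    if len(seq) != len(dotbracket):
        raise FeatureError("sequence and structure lengths differ")
    s = seq.upper().replace("T", "U")
    struct = dotbracket.replace(")", "(")
    counts = np.zeros(len(TRIPLET_CODES), dtype=float)
    index = {code: k for k, code in enumerate(TRIPLET_CODES)}
    for a, b in _stem_segments(dotbracket):
        for i in range(a, b - 2):
            code = s[i] + struct[i : i + 3]
            if code in index:  # left nucleotide must be A/C/G/U
                counts[index[code]] += 1
    total = counts.sum()
    return counts / total if total else counts


def encode(
    seq: str, structure: SecondaryStructure, anatomy: HairpinAnatomy
) -> FeatureVector:
    """Concatenate all 46 features in the frozen order."""
    ls = len(seq)
    gc = gc_percent(seq)
    scalars = (
        *mfe_features(structure.mfe, ls, gc),
        *pairing_features(anatomy, seq),
        *structural_features(structure, anatomy, seq),
    )
    triplets = triplet_features(seq, structure.dotbracket)
    return FeatureVector(np.concatenate([np.asarray(scalars), triplets]))
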