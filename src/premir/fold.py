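"""Secondary-structure prediction and hairpin anatomy.

Folding uses the ViennaRNA programmatic interface at 37 degC (RNAfold
defaults, lonely pairs allowed).  ``fold`` returns the MFE structure in
dot-bracket notation plus, optionally, three Boltzmann-ensemble
quantities used as classifier features:

* ``mfe_freq``      probability of the MFE structure in the ensemble;
* ``diversity``     ensemble diversity (expected base-pair distance
                    between two structures drawn from the ensemble), nt;
* ``mean_bp_distance``  expected base-pair distance between the ensemble
                    and the MFE structure (ensemble defect x n), nt.

``parse_anatomy`` decomposes a dot-bracket string into loops, bulges,
helices and stems; every downstream filter and feature reads from the
resulting :class:`HairpinAnatomy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

try:
    import RNA
except ImportError:  # pragma: no cover - environment guard
    RNA = None

__all__ = [
    "SecondaryStructure",
    "HairpinAnatomy",
    "fold",
    "parse_anatomy",
    "symmetry_regions",
]


@dataclass(frozen=True)
class SecondaryStructure:
    """MFE dot-bracket structure with thermodynamic annotations."""

    dotbracket: str
    mfe: float  # kcal/mol, <= 0
    mfe_freq: float | None = None  # P(MFE structure | ensemble), [0, 1]
    diversity: float | None = None  # ensemble diversity, nt
    mean_bp_distance: float | None = None  # ensemble<->MFE bp distance, nt

    def __post_init__(self) -> None:
        if self.mfe > 1e-9:
            raise ValueError(f"MFE must be <= 0, got {self.mfe}")
        if self.mfe_freq is not None and not (0.0 <= self.mfe_freq <= 1.0 + 1e-9):
            raise ValueError(f"mfe_freq outside [0,1]: {self.mfe_freq}")


@dataclass
class HairpinAnatomy:
    """Structural elements of a parsed dot-bracket string.

    ``n_base_pairs`` counts base PAIRS (not paired nucleotides);
    ``stem_region_nt`` counts every nucleotide lying in a helix, bulge or
    internal loop — for a single hairpin this is the span from the
    outermost to the innermost pair on both arms inclusive, excluding the
    terminal loop and external tails.
    """

    n_hairpin_loops: int = 0
    bulges: list[int] = field(default_factory=list)
    sym_loops: list[tuple[int, int]] = field(default_factory=list)
    asym_loops: list[tuple[int, int]] = field(default_factory=list)
    n_base_pairs: int = 0
    stem_region_nt: int = 0
    helix_runs: list[int] = field(default_factory=list)
    l_sym_rgn: int = 0
    l_rsym_rgn: int = 0
    interloop_distances: list[int] = field(default_factory=list)
    hairpin_loop_lens: list[int] = field(default_factory=list)
    external_nt: int = 0
    multiloop_nt: int = 0
    # (helix runs, separating loops) chains from outermost helix inward,
    # one per linear stem; used by symmetry_regions.
    _chains: list[list[tuple[str, object]]] = field(default_factory=list, repr=False)


def fold(seq: str, ensemble: bool = True, temperature: float = 37.0) -> SecondaryStructure:
    """Predict the MFE structure (and optionally ensemble quantities).

    T is transliterated to U before folding.  Deterministic for a fixed
    backend version and temperature.
    """
    if RNA is None:  # pragma: no cover
        raise RuntimeError(
            "ViennaRNA Python bindings not available; install the 'ViennaRNA' "
            "package (provides the 'RNA' module) to enable folding"
        )
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    rna = seq.upper().replace("T", "U")
    md = RNA.md()
    md.temperature = temperature
    fc = RNA.fold_compound(rna, md)
    db, mfe = fc.mfe()
    if not ensemble:
        return SecondaryStructure(db, min(mfe, 0.0))
    fc.exp_params_rescale(mfe)
    fc.pf()
    freq = min(max(fc.pr_structure(db), 0.0), 1.0)
    diversity = fc.mean_bp_distance()
    defect = fc.ensemble_defect(db) * len(rna)
    return SecondaryStructure(db, min(mfe, 0.0), freq, diversity, defect)


def _pair_table(dotbracket: str) -> list[int]:
    """Partner index per position (-1 if unpaired); raises on imbalance."""
    partner = [-1] * len(dotbracket)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at position {i}")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket symbol {c!r} at position {i}")
    if stack:
        raise ValueError("unbalanced dot-bracket: unclosed '('")
    return partner


def _children(partner: list[int], i: int, j: int) -> list[tuple[int, int]]:
    """Directly enclosed pairs in the open interval (i, j)."""
    kids = []
    k = i + 1
    while k < j:
        if partner[k] > k:
            kids.append((k, partner[k]))
            k = partner[k] + 1
        else:
            k += 1
    return kids


def parse_anatomy(dotbracket: str) -> HairpinAnatomy:
    """Decompose a balanced dot-bracket string into structural elements.

    Every maximal unpaired run is attributed to exactly one element:
    external tail, hairpin loop, bulge (one strand), internal loop (both
    strands, symmetric or asymmetric) or multiloop.  Multi-branched
    structures are parsed, not rejected; rejecting them is the
    prefilter's job.
    """
    partner = _pair_table(dotbracket)
    anatomy = HairpinAnatomy()
    n = len(dotbracket)

    top = _children(partner, -1, n)
    anatomy.external_nt = (n - sum(j - i + 1 for i, j in top))

    def walk(i: int, j: int, chain: list) -> None:
        """Follow the stem starting at closing pair (i, j)."""
        run = 1
        while True:
            kids = _children(partner, i, j)
            if len(kids) == 1:
                (p, q) = kids[0]
                left, right = p - i - 1, j - q - 1
                if left == 0 and right == 0:  # stacked pair
                    run += 1
                    i, j = p, q
                    continue
                anatomy.helix_runs.append(run)
                chain.append(("helix", run))
                if left == 0 or right == 0:
                    blen = max(left, right)
                    anatomy.bulges.append(blen)
                    chain.append(("bulge", blen))
                elif left == right:
                    anatomy.sym_loops.append((left, right))
                    chain.append(("sym", (left, right)))
                else:
                    anatomy.asym_loops.append((left, right))
                    chain.append(("asym", (left, right)))
                anatomy.stem_region_nt += left + right
                i, j, run = p, q, 1
            elif len(kids) == 0:  # hairpin loop
                anatomy.helix_runs.append(run)
                chain.append(("helix", run))
                anatomy.n_hairpin_loops += 1
                anatomy.hairpin_loop_lens.append(j - i - 1)
                return
            else:  # multiloop junction: chain ends, branches restart
                anatomy.helix_runs.append(run)
                chain.append(("helix", run))
                inner = (j - i - 1) - sum(q - p + 1 for p, q in kids)
                anatomy.multiloop_nt += inner
                for p, q in kids:
                    sub: list = []
                    anatomy._chains.append(sub)
                    walk(p, q, sub)
                return

    for i, j in top:
        chain: list = []
        anatomy._chains.append(chain)
        walk(i, j, chain)

    anatomy.n_base_pairs = sum(anatomy.helix_runs)
    anatomy.stem_region_nt += 2 * anatomy.n_base_pairs

    # inter-loop distances: the helix run (in bp = nt along the 5' arm)
    # separating two consecutive loops/bulges within one linear stem
    for chain in anatomy._chains:
        loop_seen = False
        for idx, (kind, val) in enumerate(chain):
            if kind == "helix":
                continue
            if loop_seen:
                # the helix between the previous loop and this one
                prev = chain[idx - 1]
                anatomy.interloop_distances.append(prev[1])
            loop_seen = True

    anatomy.l_sym_rgn, anatomy.l_rsym_rgn = symmetry_regions(anatomy)
    return anatomy


def symmetry_regions(anatomy: HairpinAnatomy) -> tuple[int, int]:
    """(longest perfect helix, longest helix chain bridged only by
    symmetric internal loops), both in base pairs.

    Bulges, asymmetric loops and multiloop junctions break a relaxed
    region; symmetric internal loops do not.
    """
    l_sym = max(anatomy.helix_runs, default=0)
    l_rsym = 0
    for chain in anatomy._chains:
        acc = 0
        for kind, val in chain:
            if kind == "helix":
                acc += val
            elif kind == "sym":
                continue  # symmetric loop: region continues
            else:
                l_rsym = max(l_rsym, acc)
                acc = 0
        l_rsym = max(l_rsym, acc)
    return l_sym, max(l_rsym, l_sym)
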