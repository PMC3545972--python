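"""Rule-based pre-filters separating hairpin-like windows from noise.

The full cascade applies fourteen structural/thermodynamic rules
(labelled a-n) to a window's MFE structure; the relaxed genome filter
applies only the strongest four (single hairpin loop, >17 pairs,
MFE < -15 kcal/mol, MFEI > 0.6) so that borderline windows are left for
the classifier to judge.  Pseudo-hairpin mining from coding sequence —
the classifier's negative class — reuses the same machinery.

All rules are evaluated on the single MFE structure; "between" bounds
are inclusive, strict inequalities strict.  Rule values needed: only
sequence + MFE structure, so mining can skip partition-function folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .features import gc_percent
from .fold import HairpinAnatomy, SecondaryStructure, fold, parse_anatomy
from .seqio import SequenceRecord, SequenceWindow, complexity_filter, gap_filter, split_windows

__all__ = ["FilterReport", "full_prefilter", "genome_prefilter", "extract_pseudo"]

MFE_MAX = -15.0  # rule (l), kcal/mol
MFEI_MIN_FULL = 0.7  # rule (m)
MFEI_MIN_GENOME = 0.6  # relaxed genome threshold


@dataclass
class FilterReport:
    passed: bool
    failed_rules: list[str] = field(default_factory=list)
    values: dict[str, float] = field(default_factory=dict)


def _measurements(
    seq: str, structure: SecondaryStructure, anatomy: HairpinAnatomy
) -> dict[str, float]:
    ls = len(seq)
    gc = gc_percent(seq)
    n_sym, n_asym, n_bulge = len(anatomy.sym_loops), len(anatomy.asym_loops), len(anatomy.bulges)
    return {
        "a": anatomy.n_hairpin_loops,
        "b": n_sym,
        "c": n_asym,
        "d": n_bulge,
        "e": n_sym + n_asym,
        "f": n_sym + n_asym + n_bulge,
        "g": anatomy.n_base_pairs,
        "h": anatomy.n_base_pairs / ls,
        "i": max((l for l, _ in anatomy.sym_loops), default=0),
        "j": max((max(l, r) for l, r in anatomy.asym_loops), default=0),
        "k": max(anatomy.bulges, default=0),
        "l": structure.mfe,
        "m": (-100.0 * structure.mfe / ls) / gc if gc > 0 else 0.0,
        "n": gc,
    }


def full_prefilter(
    seq: str, structure: SecondaryStructure, anatomy: HairpinAnatomy
) -> FilterReport:
    """Evaluate all fourteen rules (no short-circuit; every failure reported).

    (a) exactly 1 hairpin loop, (b) <6 symmetric loops, (c) <4 asymmetric
    loops, (d) <5 bulges, (e) sym+asym <8, (f) sym+asym+bulges <10,
    (g) >17 base pairs, (h) 0.3<=ANNB<=0.43, (i) each symmetric loop <5,
    (j) each asymmetric loop <6 (longer side), (k) each bulge <6,
    (l) MFE < -15 kcal/mol, (m) MFEI > 0.7, (n) 30<=GC%<=70.
    """
    v = _measurements(seq, structure, anatomy)
    checks = {
        "a": v["a"] == 1,
        "b": v["b"] < 6,
        "c": v["c"] < 4,
        "d": v["d"] < 5,
        "e": v["e"] < 8,
        "f": v["f"] < 10,
        "g": v["g"] > 17,
        "h": 0.3 <= v["h"] <= 0.43,
        "i": v["i"] < 5,
        "j": v["j"] < 6,
        "k": v["k"] < 6,
        "l": v["l"] < MFE_MAX,
        "m": v["m"] > MFEI_MIN_FULL,
        "n": 30.0 <= v["n"] <= 70.0,
    }
    failed = [r for r, ok in checks.items() if not ok]
    return FilterReport(not failed, failed, v)


def genome_prefilter(
    seq: str, structure: SecondaryStructure, anatomy: HairpinAnatomy
) -> FilterReport:
    """Relaxed filter for genome scanning: rules a, g, l and MFEI > 0.6."""
    v = _measurements(seq, structure, anatomy)
    checks = {
        "a": v["a"] == 1,
        "g": v["g"] > 17,
        "l": v["l"] < MFE_MAX,
        "m": v["m"] > MFEI_MIN_GENOME,
    }
    failed = [r for r, ok in checks.items() if not ok]
    return FilterReport(not failed, failed, {r: v[r] for r in checks})


def extract_pseudo(
    cds_records: list[SequenceRecord],
    window_len: int = 90,
    step: int = 9,
    mode: str = "full",
    limit: int | None = None,
) -> list[SequenceWindow]:
    """Mine pseudo pre-miRNA windows (the negative class) from CDS.

    Windows pass gap and complexity screening, are folded (MFE only),
    and must satisfy the chosen cascade: ``mode="full"`` applies rules
    (a)-(n); ``mode="genome"`` the relaxed a/g/l/MFEI>0.6 set.  ``limit``
    stops mining once that many windows survive.  Deterministic.
    """
    if mode not in ("full", "genome"):
        raise ValueError(f"invalid mode {mode!r}")
    rule = full_prefilter if mode == "full" else genome_prefilter
    out: list[SequenceWindow] = []
    for rec in cds_records:
        for w in split_windows(rec, window_len, step):
            if not (gap_filter(w.seq) and complexity_filter(w.seq)):
                continue
            structure = fold(w.seq, ensemble=False)
            anatomy = parse_anatomy(structure.dotbracket)
            if rule(w.seq, structure, anatomy).passed:
                out.append(w)
                if limit is not None and len(out) >= limit:
                    return out
    if not out:
        warnings.warn("no CDS window survived the pseudo-hairpin cascade")
    return out
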