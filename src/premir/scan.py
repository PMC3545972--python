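"""End-to-end genome scanning for pre-miRNA candidates.

Pipeline per window: gap screen -> complexity screen -> MFE fold ->
relaxed genome prefilter -> ensemble fold + 46-feature encoding ->
calibrated SVM probability -> keep if above threshold.  Survivors are
deduplicated (overlapping same-strand windows merged to the
highest-probability representative), flagged against known precursors,
and chained into genomic clusters at <=50 kb inter-distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from difflib import SequenceMatcher
from pathlib import Path

from .classifier import MirnaSVMResults
from .features import FeatureVector, encode
from .fold import fold, parse_anatomy
from .prefilter import genome_prefilter
from .seqio import SequenceRecord, SequenceWindow, complexity_filter, gap_filter, iter_windows

__all__ = ["Candidate", "Cluster", "scan", "dedupe", "mask_known", "cluster", "write_bed", "write_tsv"]

log = logging.getLogger(__name__)

PROB_THRESHOLD = 0.99995  # genome-scale default; relax for toy fixtures
CLUSTER_GAP = 50_000  # nt, start-to-start on one chromosome+strand
KNOWN_COVERAGE = 90.0  # %, exact-match coverage flagging a known precursor


@dataclass
class Candidate:
    window: SequenceWindow
    probability: float
    features: FeatureVector
    mfe: float
    mfei: float
    novel: bool = True
    cluster_id: int | None = None


@dataclass
class Cluster:
    source_id: str
    strand: str
    members: list[Candidate]

    @property
    def span(self) -> int:
        return self.members[-1].window.end - self.members[0].window.start


def scan(
    genome: list[SequenceRecord],
    model: MirnaSVMResults,
    threshold: float = PROB_THRESHOLD,
    window_len: int = 90,
    step: int = 9,
    strands: str = "both",
) -> list[Candidate]:
    """Scan genome records for high-probability hairpin candidates.

    Cheap screens and an MFE-only fold run first; the partition function
    is computed only for windows that pass the relaxed genome prefilter.
    Output order (and content) is independent of record order modulo
    sorting by position.
    """
    out: list[Candidate] = []
    for rec in genome:
        n_windows = n_pass = 0
        for w in iter_windows(rec, window_len, step, strands):
            n_windows += 1
            if not (gap_filter(w.seq) and complexity_filter(w.seq)):
                continue
            mfe_struct = fold(w.seq, ensemble=False)
            anatomy = parse_anatomy(mfe_struct.dotbracket)
            report = genome_prefilter(w.seq, mfe_struct, anatomy)
            if not report.passed:
                continue
            structure = fold(w.seq, ensemble=True)
            fv = encode(w.seq, structure, anatomy)
            p = float(model.predict_prob(fv)[0])
            if p > threshold:
                n_pass += 1
                out.append(Candidate(w, p, fv, structure.mfe, report.values["m"]))
        log.info("%s: %d windows, %d candidates", rec.id, n_windows, n_pass)
    out.sort(key=lambda c: (c.window.source_id, c.window.strand, c.window.start))
    return out


def dedupe(candidates: list[Candidate]) -> list[Candidate]:
    """Merge transitively overlapping same-strand windows; keep the
    highest-probability member (ties -> leftmost)."""
    out: list[Candidate] = []
    key = lambda c: (c.window.source_id, c.window.strand, c.window.start, c.window.end)
    group: list[Candidate] = []

    def flush() -> None:
        if group:
            out.append(max(group, key=lambda c: (c.probability, -c.window.start)))
            group.clear()

    for c in sorted(candidates, key=key):
        if group and (
            c.window.source_id != group[-1].window.source_id
            or c.window.strand != group[-1].window.strand
            or c.window.start >= max(g.window.end for g in group)
        ):
            flush()
        group.append(c)
    flush()
    return out


def _exact_coverage(candidate_seq: str, known_seq: str) -> float:
    """% of the candidate covered by its longest exact match to the known."""
    a = candidate_seq.upper().replace("U", "T")
    b = known_seq.upper().replace("U", "T")
    m = SequenceMatcher(None, a, b, autojunk=False).find_longest_match(0, len(a), 0, len(b))
    return 100.0 * m.size / len(a)


def mask_known(
    candidates: list[Candidate],
    known: list[SequenceRecord],
    coverage: float = KNOWN_COVERAGE,
) -> list[Candidate]:
    """Flag candidates matching a known precursor (identity 100% over
    > ``coverage``% of the candidate) as not novel.  Flags, never drops,
    so counts stay auditable."""
    for c in candidates:
        c.novel = not any(
            _exact_coverage(c.window.seq, k.seq) > coverage for k in known
        )
    return candidates


def cluster(candidates: list[Candidate], max_gap: int = CLUSTER_GAP) -> list[Cluster]:
    """Single-linkage chaining per chromosome+strand: consecutive
    candidates whose starts differ by <= ``max_gap`` share a cluster."""
    clusters: list[Cluster] = []
    current: list[Candidate] = []
    cid = 0
    ordered = sorted(
        candidates, key=lambda c: (c.window.source_id, c.window.strand, c.window.start)
    )
    for c in ordered:
        if current and (
            c.window.source_id != current[-1].window.source_id
            or c.window.strand != current[-1].window.strand
            or c.window.start - current[-1].window.start > max_gap
        ):
            clusters.append(Cluster(current[0].window.source_id, current[0].window.strand, current))
            current = []
            cid += 1
        c.cluster_id = cid
        current.append(c)
    if current:
        clusters.append(Cluster(current[0].window.source_id, current[0].window.strand, current))
    return clusters


def write_bed(candidates: list[Candidate], path: str | Path) -> None:
    """BED6; score = probability scaled to [0, 1000]."""
    with open(path, "w") as fh:
        for c in candidates:
            w = c.window
            fh.write(
                f"{w.source_id}\t{w.start}\t{w.end}\t{w.id}\t"
                f"{int(round(c.probability * 1000))}\t{w.strand}\n"
            )


def write_tsv(candidates: list[Candidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\tstrand\tprobability\tnovel\tcluster_id\tMFE\tMFEI\n")
        for c in candidates:
            w = c.window
            fh.write(
                f"{w.id}\t{w.source_id}\t{w.start}\t{w.end}\t{w.strand}\t"
                f"{c.probability:.6g}\t{c.novel}\t{c.cluster_id}\t{c.mfe:.2f}\t{c.mfei:.4f}\n"
            )
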