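"""Conservation-based candidate discovery.

Known precursors from related species are mapped onto the target genome;
loci aligning at coverage > 85% and identity > 85% are retrieved and kept
only if the fragment itself looks like a precursor: (i) folds into a
stem-loop hairpin, (ii) MFE < -15 kcal/mol, (iii) >= 18 base pairs on the
stem, (iv) no multiple loops, (v) GC content within 30-70%.

Queries nearly identical to an already-known precursor of the target
species are removed first (same coverage/identity thresholds), so the
search reports only potentially novel loci.

Alignment uses edlib infix (semi-global) edit-distance search — fast and
sensitive for short queries, and needs no external binary.  edlib reports
the best-scoring loci per query/chromosome/strand; for the near-exact
matches this module targets that is the full hit set.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .features import gc_percent
from .fold import fold, parse_anatomy
from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "HomologyHit",
    "filter_cross_species",
    "map_to_genome",
    "validate_candidate",
    "homology_pipeline",
]

COVERAGE_MIN = 85.0  # %
IDENTITY_MIN = 85.0  # %


@dataclass
class HomologyHit:
    query_id: str
    chrom: str
    start: int
    end: int
    strand: str
    coverage: float
    identity: float
    retrieved_seq: str


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _best_identity(query: str, target: str) -> float:
    """Identity (%) of the best infix alignment of the shorter sequence
    within the longer; 0 when nothing aligns within the 85% band."""
    q, t = _dna(query), _dna(target)
    if len(q) > len(t):
        q, t = t, q
    k = int(len(q) * (100.0 - IDENTITY_MIN) / 100.0)
    res = edlib.align(q, t, mode="HW", task="distance", k=k)
    if res["editDistance"] < 0:
        return 0.0
    return 100.0 * (len(q) - res["editDistance"]) / len(q)


def filter_cross_species(
    queries: list[SequenceRecord],
    known_native: list[SequenceRecord],
    coverage: float = COVERAGE_MIN,
    identity: float = IDENTITY_MIN,
) -> list[SequenceRecord]:
    """Drop cross-species precursors highly homologous to a native one.

    Coverage is measured over the query; with infix alignment a query no
    longer than the native hairpin is fully covered, otherwise coverage
    is the covered fraction of the query.
    """
    kept = []
    for q in queries:
        homologous = False
        for ref in known_native:
            cov = 100.0 * min(len(q.seq), len(ref.seq)) / len(q.seq)
            if cov > coverage and _best_identity(q.seq, ref.seq) > identity:
                homologous = True
                break
        if not homologous:
            kept.append(q)
    return kept


def map_to_genome(
    queries: list[SequenceRecord],
    genome: list[SequenceRecord],
    coverage: float = COVERAGE_MIN,
    identity: float = IDENTITY_MIN,
) -> list[HomologyHit]:
    """Best-scoring genomic loci per query at the coverage/identity
    thresholds, on both strands, duplicate loci collapsed."""
    hits: list[HomologyHit] = []
    for q in queries:
        qseq = _dna(q.seq)
        k = int(len(qseq) * (100.0 - identity) / 100.0)
        for rec in genome:
            tgt = _dna(rec.seq)
            for strand, query in (("+", qseq), ("-", reverse_complement(qseq))):
                res = edlib.align(query, tgt, mode="HW", task="locations", k=k)
                if res["editDistance"] < 0:
                    continue
                ident = 100.0 * (len(qseq) - res["editDistance"]) / len(qseq)
                if ident <= identity:
                    continue
                spans: list[tuple[int, int]] = []
                for s, e in res["locations"]:
                    s = 0 if s is None else s
                    span = (s, e + 1)
                    if any(not (span[1] <= a or span[0] >= b) for a, b in spans):
                        continue  # collapse overlapping equivalent locations
                    spans.append(span)
                    hits.append(
                        HomologyHit(
                            q.id, rec.id, span[0], span[1], strand,
                            100.0, ident, rec.seq[span[0] : span[1]],
                        )
                    )
    return hits


def validate_candidate(seq: str) -> tuple[bool, list[str]]:
    """Check a retrieved fragment against the five precursor criteria.

    Returns (passed, failed criterion labels from {"i","ii","iii","iv","v"}).
    """
    structure = fold(seq, ensemble=False)
    anatomy = parse_anatomy(structure.dotbracket)
    failed = []
    if anatomy.n_hairpin_loops != 1 or anatomy.n_base_pairs == 0:
        failed.append("i")  # must fold into one stem-loop hairpin
    if not structure.mfe < -15.0:
        failed.append("ii")
    if not anatomy.n_base_pairs >= 18:
        failed.append("iii")
    if anatomy.n_hairpin_loops > 1:
        failed.append("iv")  # multiple loops (restates i for reporting)
    if not 30.0 <= gc_percent(seq) <= 70.0:
        failed.append("v")
    return (not failed, failed)


def homology_pipeline(
    other_species: list[SequenceRecord],
    known_native: list[SequenceRecord],
    genome: list[SequenceRecord],
) -> list[HomologyHit]:
    """filter_cross_species -> map_to_genome -> validate; every returned
    hit satisfies all five criteria."""
    queries = filter_cross_species(other_species, known_native)
    hits = map_to_genome(queries, genome)
    return [h for h in hits if validate_candidate(h.retrieved_seq)[0]]
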