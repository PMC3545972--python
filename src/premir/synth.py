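"""Deterministic synthetic inputs: hairpins, CDS-like negatives, toy genomes.

Three generators stand in for the miRBase hairpin set, the NCBI CDS
download and the genome assembly, so every pipeline stage is testable
offline:

* ``make_hairpin`` builds a planted stem-loop — 5' flank + stem +
  terminal loop + reverse-complemented stem + 3' flank — with optional
  bulges, at a target GC.  Defaults sit in the band real ~90-nt
  precursors occupy (27-38 recovered pairs, i.e. pairs/LS in 0.30-0.43).
* ``make_cds_like`` emits codon-structured sequences (ATG start, biased
  codon usage, no internal stops) from which ``extract_pseudo`` mines
  the negative class.
* ``plant_genome`` embeds hairpins at recorded positions (either strand)
  in a dinucleotide-shuffled random background and returns the truth
  intervals.

All generators are pure functions of their spec/seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "FixtureSpec",
    "make_hairpin",
    "hairpin_pool",
    "make_cds_like",
    "plant_genome",
    "dinucleotide_shuffle",
]

_PAIR = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic construct (reproducible under seed)."""

    seed: int = 0
    n: int = 1
    ls: int = 90
    stem_bp: int = 30
    loop_len: int = 6
    n_bulges: int = 1
    gc: float = 0.5
    background_len: int = 50_000


def _rand_seq(rng: random.Random, n: int, gc: float, alphabet: str = "ACGU") -> str:
    ws = {"A": (1 - gc) / 2, "U": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    return "".join(rng.choices(alphabet, weights=[ws[c] for c in alphabet], k=n))


def make_hairpin(spec: FixtureSpec) -> SequenceRecord:
    """One RNA stem-loop record of length ``spec.ls``.

    The stem is perfectly complementary apart from ``n_bulges``
    single-nucleotide bulges, so the folding backend recovers nearly all
    planted pairs.  Raises ``ValueError`` when the parts exceed ``ls``.
    """
    rng = random.Random(spec.seed)
    core = 2 * spec.stem_bp + spec.loop_len + spec.n_bulges
    if core > spec.ls:
        raise ValueError(
            f"infeasible spec: stem+loop+bulges need {core} nt, window is {spec.ls}"
        )
    stem5 = _rand_seq(rng, spec.stem_bp, spec.gc)
    loop = _rand_seq(rng, spec.loop_len, 0.3)
    stem3 = "".join(_PAIR[c] for c in reversed(stem5))
    # single-nucleotide bulges inserted into the 5' arm, away from the ends
    arm5 = list(stem5)
    if spec.n_bulges:
        lo, hi = 3, spec.stem_bp - 3
        positions = sorted(rng.sample(range(lo, max(hi, lo + 1)), min(spec.n_bulges, hi - lo)))
        for off, pos in enumerate(positions):
            arm5.insert(pos + off, _rand_seq(rng, 1, 0.5))
    hairpin = "".join(arm5) + loop + stem3
    flank = spec.ls - len(hairpin)
    f5 = flank // 2
    seq = _rand_seq(rng, f5, spec.gc) + hairpin + _rand_seq(rng, flank - f5, spec.gc)
    return SequenceRecord(f"hairpin-{spec.seed}", seq)


def hairpin_pool(n: int, seed: int = 0, ls: int = 90) -> list[SequenceRecord]:
    """A varied pool of hairpin records emulating a known-precursor set.

    Stem sizes span the pairs/LS band of real precursors; loop length,
    bulge count and GC vary record to record.
    """
    rng = random.Random(seed)
    pool = []
    for k in range(n):
        spec = FixtureSpec(
            seed=rng.randrange(2**31),
            ls=ls,
            stem_bp=rng.randint(28, 36),
            loop_len=rng.randint(4, 8),
            n_bulges=rng.randint(0, 2),
            gc=rng.uniform(0.38, 0.62),
        )
        rec = make_hairpin(spec)
        pool.append(SequenceRecord(f"mir-{seed}-{k}", rec.seq))
    return pool


# codon weights: uniform over sense codons with a mild GC3 bias, fixed
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_CODON_WEIGHTS = [1.5 if c[2] in "GC" else 1.0 for c in _SENSE_CODONS]


def make_cds_like(n: int, length: int, seed: int = 0) -> list[SequenceRecord]:
    """Codon-structured DNA records: ATG start, biased codon usage,
    no internal stop codons, free of long simple repeats with high
    probability."""
    if length < 90:
        raise ValueError("CDS-like records must be at least one window long")
    from .seqio import complexity_filter

    rng = random.Random(seed)
    n_codons = (length - 3 + 2) // 3
    records = []
    for k in range(n):
        for _ in range(50):  # resample until free of simple repeats
            body = "".join(rng.choices(_SENSE_CODONS, weights=_CODON_WEIGHTS, k=n_codons))
            seq = ("ATG" + body)[:length]
            if complexity_filter(seq):
                break
        records.append(SequenceRecord(f"cds-{seed}-{k}", seq))
    return records


def dinucleotide_shuffle(seq: str, rng: random.Random) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erikson).

    The sequence is viewed as an Eulerian walk on the nucleotide graph
    whose edges are its dinucleotides; a random walk with the same edge
    multiset yields the shuffle.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # random last-edge spanning arborescence toward the terminal vertex
    # (Altschul-Erikson): pick each non-terminal vertex's final edge so the
    # final edges form a tree into `last`, then shuffle the rest.
    while True:
        finals = {}
        for v, outs in edges.items():
            if v != last:
                finals[v] = rng.choice(outs)
        # check the final edges lead every vertex to `last`
        ok = True
        for v in edges:
            if v == last:
                continue
            seen = {v}
            cur = v
            while cur != last:
                cur = finals.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    shuffled = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v != last:
            rest.remove(finals[v])
        rng.shuffle(rest)
        if v != last:
            rest.append(finals[v])
        shuffled[v] = rest
    out = [seq[0]]
    cur = seq[0]
    pos = {v: 0 for v in shuffled}
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def plant_genome(
    spec: FixtureSpec,
) -> tuple[SequenceRecord, list[tuple[int, int, str, str]]]:
    """A toy chromosome with ``spec.n`` hairpins planted at recorded loci.

    Background: random GC-matched sequence, dinucleotide-shuffled.
    Returns the record plus truth intervals (start, end, strand, name),
    0-based half-open, pairwise non-overlapping with >=100 nt spacing.
    """
    rng = random.Random(spec.seed)
    if spec.background_len < spec.n * 200:
        raise ValueError("background too short for the requested number of hairpins")
    bg = _rand_seq(rng, spec.background_len, spec.gc, alphabet="ACGT")
    bg = dinucleotide_shuffle(bg, rng)
    genome = list(bg)
    truth = []
    taken: list[tuple[int, int]] = []
    for k in range(spec.n):
        sub = FixtureSpec(
            seed=rng.randrange(2**31),
            ls=spec.ls,
            stem_bp=spec.stem_bp,
            loop_len=spec.loop_len,
            n_bulges=spec.n_bulges,
            gc=spec.gc,
        )
        hp = make_hairpin(sub).seq.replace("U", "T")
        for _ in range(1000):
            start = rng.randrange(0, spec.background_len - spec.ls)
            if all(start + spec.ls + 100 < a or start > b + 100 for a, b in taken):
                break
        else:
            raise ValueError("could not place all hairpins without overlap")
        strand = rng.choice("+-")
        insert = hp if strand == "+" else reverse_complement(hp)
        genome[start : start + spec.ls] = insert
        taken.append((start, start + spec.ls))
        truth.append((start, start + spec.ls, strand, f"planted-{k}"))
    truth.sort()
    return SequenceRecord(f"toygenome-{spec.seed}", "".join(genome)), truth
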