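"""Physical write/read channel simulation.

Models the storage medium's life cycle: guided nicking of a duplex
register, heat denaturation into ssDNA fragments whose lengths are set by
the nick positions, enzymatic toehold creation for bitwise random access, a
linear fluorescence reporter, pooling, and paired-end sequencing-read
generation with i.i.d. substitution errors.

Only substitutions are modeled (no indels, no PCR bias, no quality decay):
the decoder's acceptance surface is fragment-boundary positions, which
substitutions stress sufficiently.  Strand of origin is preserved by read
orientation, emulating a directional ssDNA library prep: sense-strand
fragments yield mate-1-forward pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codec import NickPattern
from .design import ReferenceRegister
from .seqcore import ANTISENSE, SENSE, Interval, constant_quality, revcomp, write_fastq

DEFAULT_READ_LEN = 250  # sequencing cycles per mate
DEFAULT_DISSOCIATION_NT = 20  # inter-nick fragments up to this length melt off


class NoReleaseError(RuntimeError):
    """The inter-nick fragment is too long to dissociate; no toehold forms."""


@dataclass(frozen=True)
class NickedDuplex:
    register_id: str
    length: int
    sense_cuts: tuple  # sorted sense-frame bond coordinates
    antisense_cuts: tuple

    def __post_init__(self) -> None:
        for cuts in (self.sense_cuts, self.antisense_cuts):
            if list(cuts) != sorted(set(cuts)):
                raise ValueError("cut bonds must be sorted and unique")
            if cuts and not (0 < cuts[0] and cuts[-1] < self.length):
                raise ValueError("cut bonds must lie strictly inside the register")


@dataclass(frozen=True)
class Fragment:
    """One ssDNA molecule, as a sense-frame interval plus its strand."""

    register_id: str
    start: int
    end: int
    strand: str


@dataclass
class FragmentSet:
    fragments: list  # Fragment, duplicates = multiplicity

    def __len__(self) -> int:
        return len(self.fragments)

    def lengths(self, register_id: str, strand: str) -> list:
        return sorted(
            f.end - f.start
            for f in self.fragments
            if f.register_id == register_id and f.strand == strand
        )


@dataclass(frozen=True)
class ToeholdDuplex:
    register_id: str
    gap: Interval  # exposed ssDNA region, sense frame
    strand: str


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    truth: Fragment  # provenance, for tests only


@dataclass
class ReadPairBatch:
    pairs: list

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------

def apply_pattern(
    reg: ReferenceRegister,
    pattern: NickPattern,
    nick_fail_prob: float = 0.0,
    rng: np.random.Generator | None = None,
) -> NickedDuplex:
    """Nick all sites of *reg* addressed by *pattern*, in parallel.

    Symbol 1 cuts the sense strand at the site's bond, 2 the antisense
    strand, 0 leaves the ground state.  ``nick_fail_prob`` optionally drops
    each requested nick independently (default 0: the enzyme completes).
    """
    if pattern.register_id != reg.id:
        raise ValueError(f"pattern targets {pattern.register_id}, register is {reg.id}")
    if len(pattern.symbols) != reg.n_sites:
        raise ValueError("pattern width must equal the register site count")
    if nick_fail_prob and rng is None:
        rng = np.random.default_rng()
    sense, anti = [], []
    for site, sym in zip(reg.sites, pattern.symbols):
        if sym == 0:
            continue
        if nick_fail_prob and rng.random() < nick_fail_prob:
            continue
        (sense if sym == 1 else anti).append(site.cut_bond)
    return NickedDuplex(reg.id, reg.length, tuple(sense), tuple(anti))


def denature(d: NickedDuplex) -> FragmentSet:
    """Melt the duplex: each strand splits at its cut bonds.

    Per strand the fragments are the maximal intervals between consecutive
    cuts and the register ends; they tile [0, L) exactly.
    """
    frags = []
    for strand, cuts in ((SENSE, d.sense_cuts), (ANTISENSE, d.antisense_cuts)):
        edges = [0, *cuts, d.length]
        frags.extend(
            Fragment(d.register_id, a, b, strand) for a, b in zip(edges, edges[1:])
        )
    return FragmentSet(frags)


def make_toehold(
    reg: ReferenceRegister,
    site_a: int,
    site_b: int,
    strand: str = SENSE,
    dissociation_threshold: int = DEFAULT_DISSOCIATION_NT,
) -> ToeholdDuplex:
    """Two nearby same-strand nicks release the inter-nick fragment.

    Site arguments are 1-based ordinals.  The released gap is the exposed
    ssDNA toehold; fragments longer than ``dissociation_threshold`` stay
    annealed (mirroring the >= 25 bp stability rule for data nicks).
    """
    if site_a == site_b:
        raise ValueError("a toehold needs two distinct nicks")
    by_ord = {s.ordinal: s for s in reg.sites}
    try:
        a, b = by_ord[site_a].cut_bond, by_ord[site_b].cut_bond
    except KeyError as exc:
        raise ValueError(f"unknown site ordinal {exc}") from exc
    lo, hi = min(a, b), max(a, b)
    if hi - lo > dissociation_threshold:
        raise NoReleaseError(
            f"inter-nick distance {hi - lo} nt > {dissociation_threshold} nt: "
            "fragment stays annealed"
        )
    return ToeholdDuplex(reg.id, Interval(lo, hi), strand)


def reporter_readout(toehold_fraction: float) -> float:
    """Normalized fluorescence of the toehold reporter.

    Linear, unit slope, zero intercept: signal equals the fraction of
    registers carrying the toehold.
    """
    if not 0.0 <= toehold_fraction <= 1.0:
        raise ValueError("toehold fraction must be in [0, 1]")
    return float(toehold_fraction)


# ---------------------------------------------------------------------------
# Sequencing
# ---------------------------------------------------------------------------

def _mutate(seq: str, err_rate: float, rng: np.random.Generator) -> str:
    if err_rate <= 0.0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < err_rate)[0]
    for i in hits:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def sim_reads(
    fs: FragmentSet,
    references: dict,
    coverage: int = 1,
    read_len: int = DEFAULT_READ_LEN,
    err_rate: float = 0.0,
    seed: int = 0,
    phred: int = 30,
) -> ReadPairBatch:
    """Paired-end reads from every ssDNA fragment, ``coverage`` pairs each.

    Mate 1 reads from the fragment's 5' end, mate 2 from its 3' end as the
    reverse complement; both are truncated to min(read_len, fragment
    length).  Substitution errors are i.i.d. at ``err_rate``.  Deterministic
    for a fixed seed.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if not 0.0 <= err_rate < 0.1:
        raise ValueError("err_rate must be in [0, 0.1)")
    rng = np.random.default_rng(seed)
    pairs = []
    for fi, frag in enumerate(fs.fragments):
        ref = references[frag.register_id]
        piece = ref[frag.start : frag.end]
        molecule = piece if frag.strand == SENSE else revcomp(piece)
        n = min(read_len, len(molecule))
        for c in range(coverage):
            seq1 = _mutate(molecule[:n], err_rate, rng)
            seq2 = _mutate(revcomp(molecule)[:n], err_rate, rng)
            rid = f"{frag.register_id}:{frag.start}-{frag.end}:{frag.strand}:{fi}:{c}"
            pairs.append(
                ReadPair(rid, seq1, constant_quality(n, phred), seq2, constant_quality(n, phred), frag)
            )
    return ReadPairBatch(pairs)


def pool(*items):
    """Multiset union of fragment sets or read batches; provenance kept."""
    if not items:
        raise ValueError("nothing to pool")
    if isinstance(items[0], FragmentSet):
        return FragmentSet([f for fs in items for f in fs.fragments])
    if isinstance(items[0], ReadPairBatch):
        return ReadPairBatch([p for b in items for p in b.pairs])
    raise TypeError(f"cannot pool {type(items[0]).__name__}")


def write_fastq_pair(batch: ReadPairBatch, r1_path, r2_path) -> None:
    write_fastq(r1_path, [(p.read_id, p.seq1, p.qual1) for p in batch.pairs])
    write_fastq(r2_path, [(p.read_id, p.seq2, p.qual2) for p in batch.pairs])


def read_fastq_pair(r1_path, r2_path) -> ReadPairBatch:
    from .seqcore import read_fastq

    r1, r2 = read_fastq(r1_path), read_fastq(r2_path)
    if len(r1) != len(r2):
        raise ValueError("mate files have different record counts")
    pairs = []
    for (id1, s1, q1), (id2, s2, q2) in zip(r1, r2):
        if id1 != id2:
            raise ValueError(f"mate id mismatch: {id1} vs {id2}")
        pairs.append(ReadPair(id1, s1, q1, s2, q2, truth=None))
    return ReadPairBatch(pairs)
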