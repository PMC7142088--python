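"""Register and guide design under the nicking-storage sequence constraints.

A *register* is a known genomic window (default 450 bp) carrying an ordered
set of designed nick sites.  Each site is addressed by a 16-nt ssDNA guide
that directs a programmable nickase to cut one strand between guide
positions 10 and 11.  Guides must satisfy, within a register (and panel):

* length exactly 16 nt;
* GC fraction in [0.20, 0.60];
* no run of G longer than 3;
* pairwise Hamming distance >= 8;
* consecutive cut bonds >= 25 nt apart;
* the guide 16-mer occurs exactly once in the source genome (both strands).

Cut-bond mapping (bond coordinates are sense-frame, see `seqcore`):

    sense-target guide, footprint [f, f+16)      ->  bond f + 10
    antisense-target guide, footprint [f, f+16)  ->  bond f + 6

The antisense mapping follows from the guide running antiparallel: its 5'
end sits at the footprint's right edge in the sense frame, so guide
positions 10|11 fall 6 nt from the footprint start.  A base-by-base diagram
is in docs/methods.md.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .seqcore import (
    ANTISENSE,
    SENSE,
    Interval,
    gc_fraction,
    revcomp,
    validate_dna,
)

GUIDE_LEN = 16
CUT_OFFSET = {SENSE: 10, ANTISENSE: 6}
GC_BOUNDS = (0.20, 0.60)
MAX_G_RUN = 3
MIN_HAMMING = 8
MIN_SPACING = 25
DEFAULT_REGISTER_LENGTH = 450
DEFAULT_END_MARGIN = 20


class DesignInfeasibleError(RuntimeError):
    """No window satisfied the design constraints; names the binding one."""


class PartialPanelError(RuntimeError):
    """Panel design fell short; carries the registers achieved so far."""

    def __init__(self, msg: str, achieved: list["ReferenceRegister"]):
        super().__init__(msg)
        self.achieved = achieved


@dataclass(frozen=True)
class Guide:
    """A 16-nt guide addressing one strand of a register."""

    sequence: str
    target_strand: str
    footprint: Interval  # sense-frame, length 16

    def __post_init__(self) -> None:
        if len(self.sequence) != GUIDE_LEN or len(self.footprint) != GUIDE_LEN:
            raise ValueError("guide sequence and footprint must be 16 nt")

    @property
    def cut_bond(self) -> int:
        return self.footprint.start + CUT_OFFSET[self.target_strand]


@dataclass(frozen=True)
class NickSite:
    """One addressable nick position; both strands share the cut bond."""

    ordinal: int  # 1-based within the register
    cut_bond: int  # sense-frame bond coordinate
    guides: dict  # strand -> Guide; sense always present, antisense if two-sided

    @property
    def guide(self) -> Guide:
        return self.guides[SENSE]

    @property
    def two_sided(self) -> bool:
        return ANTISENSE in self.guides


@dataclass
class ReferenceRegister:
    id: str
    sequence: str
    origin: Interval
    sites: list  # ordered NickSite, ascending cut_bond

    def __post_init__(self) -> None:
        self.sequence = validate_dna(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def cut_bonds(self) -> list:
        return [s.cut_bond for s in self.sites]

    @property
    def two_sided(self) -> bool:
        return all(s.two_sided for s in self.sites)

    def all_guides(self) -> list:
        out = []
        for s in self.sites:
            out.extend(s.guides[k] for k in (SENSE, ANTISENSE) if k in s.guides)
        return out


@dataclass
class RegisterPanel:
    registers: list
    pairwise_similarity: np.ndarray

    def __iter__(self):
        return iter(self.registers)

    def __len__(self) -> int:
        return len(self.registers)

    @property
    def site_counts(self) -> list:
        return [r.n_sites for r in self.registers]


# ---------------------------------------------------------------------------
# Elementary checks
# ---------------------------------------------------------------------------

def check_guide(seq: str) -> list:
    """Return every violated single-guide constraint (empty list = pass)."""
    s = validate_dna(seq)
    if len(s) != GUIDE_LEN:
        raise ValueError(f"guide must be {GUIDE_LEN} nt, got {len(s)}")
    violations = []
    gc = gc_fraction(s)
    if not GC_BOUNDS[0] <= gc <= GC_BOUNDS[1]:
        violations.append(f"GC {gc:.0%} outside [{GC_BOUNDS[0]:.0%}, {GC_BOUNDS[1]:.0%}]")
    if "G" * (MAX_G_RUN + 1) in s:
        violations.append(f"G-run longer than {MAX_G_RUN}")
    return violations


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def cut_bond_for(footprint: Interval, target_strand: str) -> int:
    """Sense-frame bond coordinate cut by a guide with this footprint."""
    if len(footprint) != GUIDE_LEN:
        raise ValueError("guide footprint must be 16 nt")
    return footprint.start + CUT_OFFSET[target_strand]


# ---------------------------------------------------------------------------
# Register design
# ---------------------------------------------------------------------------

def _kmer_counter(genome: str, k: int = GUIDE_LEN) -> Counter:
    return Counter(genome[i : i + k] for i in range(len(genome) - k + 1))


def _guides_at(register_seq: str, bond: int, two_sided: bool) -> dict:
    """Candidate guide(s) whose cut falls on *bond* of the register."""
    guides = {}
    f = bond - CUT_OFFSET[SENSE]
    guides[SENSE] = Guide(register_seq[f : f + GUIDE_LEN], SENSE, Interval(f, f + GUIDE_LEN))
    if two_sided:
        f = bond - CUT_OFFSET[ANTISENSE]
        guides[ANTISENSE] = Guide(
            revcomp(register_seq[f : f + GUIDE_LEN]), ANTISENSE, Interval(f, f + GUIDE_LEN)
        )
    return guides


def _genome_frame_16mers(register_seq: str, guides: dict) -> list:
    return [register_seq[g.footprint.start : g.footprint.end] for g in guides.values()]


def design_register(
    genome: str,
    length: int = DEFAULT_REGISTER_LENGTH,
    n_sites: int = 10,
    min_spacing: int = MIN_SPACING,
    min_hamming: int = MIN_HAMMING,
    seed: int = 0,
    two_sided: bool = False,
    end_margin: int = DEFAULT_END_MARGIN,
    window_stride: int = 50,
    register_id: str = "R1",
    search_start: int | None = None,
    kmer_counts: Counter | None = None,
) -> ReferenceRegister:
    """Greedy left-to-right site selection in the first feasible window.

    Windows of ``length`` are scanned from a seeded offset; within a window
    candidate cut bonds are taken left to right and a site is accepted as
    soon as its guide(s) pass all constraints against the sites already
    chosen.  No backtracking: the first window yielding ``n_sites`` wins,
    which makes the design reproducible for a fixed seed.
    """
    genome = validate_dna(genome)
    lo_bond = max(CUT_OFFSET[SENSE], end_margin)
    hi_bond = min(length - (GUIDE_LEN - CUT_OFFSET[SENSE]), length - end_margin)
    if two_sided:
        # antisense footprint [b-6, b+10) must also fit
        lo_bond = max(lo_bond, CUT_OFFSET[ANTISENSE])
        hi_bond = min(hi_bond, length - (GUIDE_LEN - CUT_OFFSET[ANTISENSE]))
    if (n_sites - 1) * min_spacing > hi_bond - lo_bond:
        raise DesignInfeasibleError(
            f"spacing: {n_sites} sites x {min_spacing} nt cannot fit in the "
            f"usable bond range [{lo_bond}, {hi_bond}] of a {length} nt register"
        )
    if kmer_counts is None:
        kmer_counts = _kmer_counter(genome)

    rng = np.random.default_rng(seed)
    if search_start is None:
        search_start = int(rng.integers(0, window_stride))
    reject_reasons: Counter = Counter()

    for w in range(search_start, len(genome) - length + 1, window_stride):
        window = genome[w : w + length]
        sites: list = []
        chosen_guides: list = []
        bond = lo_bond
        while bond <= hi_bond and len(sites) < n_sites:
            guides = _guides_at(window, bond, two_sided)
            reason = None
            for g in guides.values():
                v = check_guide(g.sequence)
                if v:
                    reason = v[0]
                    break
                if any(hamming(g.sequence, c.sequence) < min_hamming for c in chosen_guides):
                    reason = "pairwise Hamming"
                    break
            if reason is None:
                for mer in _genome_frame_16mers(window, guides):
                    if kmer_counts[mer] != 1 or kmer_counts[revcomp(mer)] > 0:
                        reason = "genome uniqueness"
                        break
            if reason is None and two_sided:
                if hamming(guides[SENSE].sequence, guides[ANTISENSE].sequence) < min_hamming:
                    reason = "pairwise Hamming"
            if reason is None:
                sites.append(NickSite(len(sites) + 1, bond, guides))
                chosen_guides.extend(guides.values())
                bond += min_spacing
            else:
                reject_reasons[reason] += 1
                bond += 1
        if len(sites) == n_sites:
            return ReferenceRegister(
                id=register_id,
                sequence=window,
                origin=Interval(w, w + length),
                sites=sites,
            )
    binding = reject_reasons.most_common(1)
    detail = f"; binding constraint: {binding[0][0]}" if binding else ""
    raise DesignInfeasibleError(
        f"no {length} nt window hosts {n_sites} sites at spacing {min_spacing}{detail}"
    )


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

_aligner = Align.PairwiseAligner()
_aligner.mode = "local"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -1


def similarity(a, b) -> float:
    """Best local-alignment score (unit match, -1 mismatch/gap) over min length.

    Accepts registers or raw sequences; symmetric; identical sequences -> 1.0.
    """
    sa = a.sequence if hasattr(a, "sequence") else validate_dna(a)
    sb = b.sequence if hasattr(b, "sequence") else validate_dna(b)
    score = _aligner.score(sa, sb)
    return max(0.0, score) / min(len(sa), len(sb))


def design_panel(
    genome: str,
    count: int,
    length: int = DEFAULT_REGISTER_LENGTH,
    per_register_sites=None,
    similarity_threshold: float = 0.50,
    seed: int = 0,
    two_sided: bool = False,
    **register_kwargs,
) -> RegisterPanel:
    """Design ``count`` orthogonal registers in genome order.

    Registers occupy disjoint genome windows, share no guide 16-mer, and all
    off-diagonal similarities are strictly below ``similarity_threshold``.
    The default site allocation (10, 5, 6, 5, 6, ...) mirrors a 5-register /
    32-site layout.
    """
    genome = validate_dna(genome)
    if per_register_sites is None:
        base = [10, 5, 6, 5, 6]
        per_register_sites = [base[i % len(base)] for i in range(count)]
    if len(per_register_sites) != count:
        raise ValueError("per_register_sites must have one entry per register")
    kmer_counts = _kmer_counter(genome)
    registers: list = []
    used_mers: set = set()
    cursor = 0
    stride = register_kwargs.get("window_stride", 50)
    while len(registers) < count:
        idx = len(registers)
        try:
            reg = design_register(
                genome,
                length=length,
                n_sites=per_register_sites[idx],
                seed=seed + idx,
                two_sided=two_sided,
                register_id=f"R{idx}",
                search_start=cursor,
                kmer_counts=kmer_counts,
                **register_kwargs,
            )
        except DesignInfeasibleError as exc:
            raise PartialPanelError(
                f"achieved {len(registers)}/{count} registers: {exc}", registers
            ) from exc
        mers = {
            reg.sequence[g.footprint.start : g.footprint.end] for g in reg.all_guides()
        }
        ok = not (mers & used_mers) and all(
            similarity(reg, prev) < similarity_threshold for prev in registers
        )
        if ok:
            registers.append(reg)
            used_mers |= mers
            cursor = reg.origin.end
        else:
            cursor = reg.origin.start + stride
        if cursor > len(genome) - length:
            raise PartialPanelError(
                f"achieved {len(registers)}/{count} registers: genome exhausted",
                registers,
            )
    sim = np.eye(count)
    for i in range(count):
        for j in range(i + 1, count):
            sim[i, j] = sim[j, i] = similarity(registers[i], registers[j])
    return RegisterPanel(registers, sim)


# ---------------------------------------------------------------------------
# Fragment-length prediction and validation
# ---------------------------------------------------------------------------

def expected_fragments(reg: ReferenceRegister, pattern) -> dict:
    """Per-strand sorted ssDNA lengths after nicking *pattern* and denaturing.

    Symbol 1 cuts the sense strand, 2 the antisense strand, 0 neither.  A
    strand with cut bonds ``b1 < ... < bk`` melts into ``k+1`` fragments of
    lengths ``b1, b2-b1, ..., L-bk``; an uncut strand stays full length.
    """
    symbols = getattr(pattern, "symbols", pattern)
    if len(symbols) != reg.n_sites:
        raise ValueError(
            f"pattern width {len(symbols)} != register site count {reg.n_sites}"
        )
    cuts = {SENSE: [], ANTISENSE: []}
    for site, sym in zip(reg.sites, symbols):
        if sym == 1:
            cuts[SENSE].append(site.cut_bond)
        elif sym == 2:
            cuts[ANTISENSE].append(site.cut_bond)
        elif sym != 0:
            raise ValueError(f"unknown symbol {sym!r}")
    out = {}
    for strand, bonds in cuts.items():
        edges = [0] + sorted(bonds) + [reg.length]
        out[strand] = sorted(b - a for a, b in zip(edges, edges[1:]))
    return out


def validate_register(
    reg: ReferenceRegister,
    genome: str | None = None,
    min_spacing: int = MIN_SPACING,
    min_hamming: int = MIN_HAMMING,
) -> list:
    """Independent post-hoc recheck of every design constraint, from scratch."""
    problems = []
    guides = reg.all_guides()
    for g in guides:
        if len(g.sequence) != GUIDE_LEN:
            problems.append(f"{g.sequence}: wrong length")
            continue
        for v in check_guide(g.sequence):
            problems.append(f"{g.sequence}: {v}")
        # guide must reproduce from the register sequence
        window = reg.sequence[g.footprint.start : g.footprint.end]
        expect = window if g.target_strand == SENSE else revcomp(window)
        if g.sequence != expect:
            problems.append(f"{g.sequence}: does not match register footprint")
        if g.cut_bond != cut_bond_for(g.footprint, g.target_strand):
            problems.append(f"{g.sequence}: cut bond inconsistent with footprint")
    for i in range(len(guides)):
        for j in range(i + 1, len(guides)):
            if hamming(guides[i].sequence, guides[j].sequence) < min_hamming:
                problems.append(
                    f"guides {i},{j}: Hamming < {min_hamming}"
                )
    bonds = reg.cut_bonds
    if bonds != sorted(bonds):
        problems.append("site ordinals not ascending in cut bond")
    for a, b in zip(bonds, bonds[1:]):
        if b - a < min_spacing:
            problems.append(f"cut bonds {a},{b}: spacing {b - a} < {min_spacing}")
    if genome is not None:
        counts = _kmer_counter(validate_dna(genome))
        for g in guides:
            mer = reg.sequence[g.footprint.start : g.footprint.end]
            if counts[mer] != 1 or counts[revcomp(mer)] > 0:
                problems.append(f"{g.sequence}: footprint 16-mer not genome-unique")
    return problems


def kmer_census(genome: str, k: int) -> int:
    """Exact count of distinct k-mers over a sliding window."""
    genome = validate_dna(genome)
    if not 1 <= k <= len(genome):
        raise ValueError("k out of range")
    return len({genome[i : i + k] for i in range(len(genome) - k + 1)})


# ---------------------------------------------------------------------------
# Serialization (design JSON + BED track)
# ---------------------------------------------------------------------------

def _guide_to_dict(g: Guide) -> dict:
    return {
        "sequence": g.sequence,
        "target_strand": g.target_strand,
        "footprint": [g.footprint.start, g.footprint.end],
    }


def register_to_dict(reg: ReferenceRegister) -> dict:
    return {
        "id": reg.id,
        "sequence": reg.sequence,
        "origin": [reg.origin.start, reg.origin.end],
        "sites": [
            {
                "ordinal": s.ordinal,
                "cut_bond": s.cut_bond,
                "guides": {k: _guide_to_dict(g) for k, g in s.guides.items()},
            }
            for s in reg.sites
        ],
    }


def register_from_dict(d: dict) -> ReferenceRegister:
    sites = []
    for sd in d["sites"]:
        guides = {
            k: Guide(gd["sequence"], gd["target_strand"], Interval(*gd["footprint"]))
            for k, gd in sd["guides"].items()
        }
        sites.append(NickSite(sd["ordinal"], sd["cut_bond"], guides))
    return ReferenceRegister(d["id"], d["sequence"], Interval(*d["origin"]), sites)


def panel_to_dict(panel: RegisterPanel) -> dict:
    return {
        "registers": [register_to_dict(r) for r in panel.registers],
        "pairwise_similarity": np.asarray(panel.pairwise_similarity).tolist(),
    }


def panel_from_dict(d: dict) -> RegisterPanel:
    regs = [register_from_dict(rd) for rd in d["registers"]]
    return RegisterPanel(regs, np.asarray(d["pairwise_similarity"]))


def save_design(panel: RegisterPanel, path, header: dict | None = None) -> None:
    doc = {"format": "punchcard-design/1", "bit_order": "msb-first"}
    if header:
        doc.update(header)
    doc.update(panel_to_dict(panel))
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_design(path) -> RegisterPanel:
    with open(path) as fh:
        return panel_from_dict(json.load(fh))


def write_site_bed(panel: RegisterPanel, path) -> None:
    """Nick-site track: one BED line per guide footprint (0-based half-open)."""
    with open(path, "w") as fh:
        for reg in panel:
            for s in reg.sites:
                for strand_key, g in sorted(s.guides.items()):
                    strand = "+" if strand_key == SENSE else "-"
                    fh.write(
                        f"{reg.id}\t{g.footprint.start}\t{g.footprint.end}\t"
                        f"{s.ordinal}\t0\t{strand}\n"
                    )
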