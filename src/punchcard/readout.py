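"""Decoding: reference alignment, fragment inference, insert-size gating,
boundary-evidence accumulation, nick calling, and payload reconstruction.

The aligner is a bespoke seed-and-extend over the known register panel
(references are a handful of ~450 nt sequences): exact 20-mer seeds are
indexed for both orientations of every register, candidate placements are
extended by mismatch counting, and the fewest-mismatch placement wins.
Ties across registers are discarded as ambiguous — correctness over yield.

Nick calling never reads coverage depth directly; the sufficient statistic
is the count of read-supported fragment boundaries within +-1 nt of each
designed cut bond.  A nick whose own fragment went unobserved is still
called from its neighbours' boundaries (hole inference), and sites with no
evidence at all are declared 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from .codec import (
    NickPattern,
    PlateLayout,
    bytes_from_blocks,
    collect_layout,
)
from .design import RegisterPanel
from .seqcore import ANTISENSE, SENSE, revcomp

SEED_LEN = 20
MIN_READ_LEN = 20  # reads shorter than this are dropped (MINLEN-style filter)
DEFAULT_TOL = 1  # +-1 nt boundary/insert-size tolerance
DEFAULT_TAU = 1  # reads of evidence required to call a nick


class DecodingError(RuntimeError):
    """Unresolvable decoding state; the message names the well and site."""


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    register_id: str
    start: int
    end: int
    orientation: str  # "forward" | "reverse"
    mismatches: int


@dataclass(frozen=True)
class InferredFragment:
    register_id: str
    start: int
    end: int
    strand: str

    @property
    def template_length(self) -> int:
        return self.end - self.start


@dataclass
class EvidenceTable:
    """Per-register, per-site, per-strand boundary counts.

    ``sites[register_id][ordinal][strand]`` counts kept fragments with an
    endpoint within tolerance of that site's cut bond; register ends are
    tallied separately and never feed site evidence.
    """

    sites: dict
    end_counts: dict  # register_id -> int
    kept_fragments: int = 0


class ReferenceIndex:
    """Exact-seed index over a register panel, both orientations."""

    def __init__(self, references: dict, seed_len: int = SEED_LEN):
        # accept registers or raw sequences
        self.references = {
            rid: (ref.sequence if hasattr(ref, "sequence") else ref)
            for rid, ref in references.items()
        }
        self.seed_len = seed_len
        self._index: dict = {}
        self._oriented = {}
        for rid, seq in self.references.items():
            for orientation, s in ((
                "forward", seq), ("reverse", revcomp(seq))):
                self._oriented[rid, orientation] = s
                for i in range(len(s) - seed_len + 1):
                    self._index.setdefault(s[i : i + seed_len], []).append(
                        (rid, orientation, i)
                    )

    def lookup(self, kmer: str):
        return self._index.get(kmer, ())

    def oriented(self, rid: str, orientation: str) -> str:
        return self._oriented[rid, orientation]


def _mismatches(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def align(read: str, index: ReferenceIndex, max_mismatch: int = 10) -> AlignmentRecord | None:
    """Seed-and-extend a read against the panel; None = unmapped/ambiguous."""
    k = index.seed_len
    if len(read) < k:
        return None
    offsets = list(range(0, len(read) - k + 1, k // 2))
    if offsets[-1] != len(read) - k:
        offsets.append(len(read) - k)
    candidates = set()
    for off in offsets:
        for rid, orientation, pos in index.lookup(read[off : off + k]):
            start = pos - off
            ref = index.oriented(rid, orientation)
            if 0 <= start and start + len(read) <= len(ref):
                candidates.add((rid, orientation, start))
        if candidates:
            break  # leftmost clean seed suffices; later offsets are fallbacks
    best, best_mm, tie_other_register = None, max_mismatch + 1, False
    for rid, orientation, start in sorted(candidates):
        ref = index.oriented(rid, orientation)
        mm = _mismatches(read, ref[start : start + len(read)], best_mm)
        if mm < best_mm:
            best, best_mm, tie_other_register = (rid, orientation, start), mm, False
        elif mm == best_mm and best is not None and rid != best[0]:
            tie_other_register = True
    if best is None or best_mm > max_mismatch or tie_other_register:
        return None
    rid, orientation, start = best
    L = len(index.references[rid])
    if orientation == "forward":
        s, e = start, start + len(read)
    else:
        s, e = L - start - len(read), L - start
    return AlignmentRecord("", rid, s, e, orientation, best_mm)


def infer_fragment(mate1: AlignmentRecord, mate2: AlignmentRecord) -> InferredFragment:
    """Fragment spanned by a concordant pair; strand from mate-1 orientation."""
    if mate1.register_id != mate2.register_id:
        raise DecodingError(
            f"discordant pair: registers {mate1.register_id} vs {mate2.register_id}"
        )
    if mate1.orientation == mate2.orientation:
        raise DecodingError("discordant pair: mates share an orientation")
    start = min(mate1.start, mate2.start)
    end = max(mate1.end, mate2.end)
    strand = SENSE if mate1.orientation == "forward" else ANTISENSE
    return InferredFragment(mate1.register_id, start, end, strand)


def expected_length_set(reg) -> set:
    """All achievable fragment lengths: inter-cut, cut-to-end, full length."""
    edges = [0, *reg.cut_bonds, reg.length]
    return {b - a for i, a in enumerate(edges) for b in edges[i + 1 :]}


def size_gate(frag: InferredFragment, expected_lengths: set, tol: int = DEFAULT_TOL) -> bool:
    """Keep a fragment iff its template length is within +-tol of an expected size."""
    t = frag.template_length
    return any(abs(t - e) <= tol for e in expected_lengths)


def accumulate_evidence(
    fragments, registers: dict, tol: int = DEFAULT_TOL
) -> EvidenceTable:
    """Tally fragment-boundary support at each designed cut bond.

    Each kept fragment [a, b) on strand s contributes one count at every
    site whose cut bond lies within ``tol`` of a, and one at every site
    within ``tol`` of b.  Boundaries at the register ends are counted
    separately (an uncut strand evidences nothing at any site).
    """
    table = EvidenceTable(
        sites={
            rid: {s.ordinal: {SENSE: 0, ANTISENSE: 0} for s in reg.sites}
            for rid, reg in registers.items()
        },
        end_counts={rid: 0 for rid in registers},
    )
    for frag in fragments:
        reg = registers[frag.register_id]
        table.kept_fragments += 1
        for endpoint in (frag.start, frag.end):
            if endpoint <= tol or endpoint >= reg.length - tol:
                table.end_counts[frag.register_id] += 1
                continue
            for site in reg.sites:
                if abs(site.cut_bond - endpoint) <= tol:
                    table.sites[frag.register_id][site.ordinal][frag.strand] += 1
    return table


def call_pattern(
    table: EvidenceTable, reg, mode: str = "binary", tau: int = DEFAULT_TAU
) -> tuple:
    """Call the per-site nick states for one register.

    Binary mode: a site is 1 iff boundary evidence on either strand reaches
    ``tau``; evidence reaching ``tau`` on *both* strands of a one-sided
    design is a conflict (flagged, never silently resolved).  Ternary mode:
    1 for sense-only evidence, 2 for antisense-only, 0 for neither;
    both-strand evidence is a conflict.  Uncovered sites are declared 0.

    Returns ``(NickPattern, conflicts)`` with conflicts a list of ordinals.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    symbols, conflicts = [], []
    for site in reg.sites:
        counts = table.sites[reg.id][site.ordinal]
        s_hit = counts[SENSE] >= tau
        a_hit = counts[ANTISENSE] >= tau
        if mode == "binary":
            symbols.append(1 if (s_hit or a_hit) else 0)
            if s_hit and a_hit:
                conflicts.append(site.ordinal)
        elif mode == "ternary":
            if s_hit and a_hit:
                conflicts.append(site.ordinal)
                symbols.append(0)
            else:
                symbols.append(1 if s_hit else 2 if a_hit else 0)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return NickPattern(reg.id, tuple(symbols), mode), conflicts


# ---------------------------------------------------------------------------
# Well / run level decoding
# ---------------------------------------------------------------------------

def decode_well(
    batch,
    registers: dict,
    mode: str = "binary",
    tau: int = DEFAULT_TAU,
    tol: int = DEFAULT_TOL,
    index: ReferenceIndex | None = None,
    well: str = "?",
) -> tuple:
    """Decode one well's read pairs against the registers it may contain.

    Returns ``(patterns_by_register_id, stats)``; raises
    :class:`DecodingError` on conflicts or a register with no reads at all.
    """
    if index is None:
        index = ReferenceIndex(registers)
    stats = {
        "pairs": len(batch.pairs),
        "unmapped": 0,
        "discordant": 0,
        "size_rejected": 0,
        "short": 0,
        "kept": 0,
    }
    expected = {rid: expected_length_set(reg) for rid, reg in registers.items()}
    fragments = []
    for pair in batch.pairs:
        if len(pair.seq1) < MIN_READ_LEN or len(pair.seq2) < MIN_READ_LEN:
            stats["short"] += 1
            continue
        a1 = align(pair.seq1, index)
        a2 = align(pair.seq2, index)
        if a1 is None or a2 is None:
            stats["unmapped"] += 1
            continue
        if a1.register_id not in registers or a2.register_id not in registers:
            stats["discordant"] += 1  # mapped outside this well's contents
            continue
        try:
            frag = infer_fragment(a1, a2)
        except DecodingError:
            stats["discordant"] += 1
            continue
        if not size_gate(frag, expected[frag.register_id], tol):
            stats["size_rejected"] += 1
            continue
        fragments.append(frag)
    stats["kept"] = len(fragments)
    table = accumulate_evidence(fragments, registers, tol)
    patterns = {}
    for rid, reg in registers.items():
        if not any(f.register_id == rid for f in fragments):
            raise DecodingError(f"well {well}: no usable reads for register {rid}")
        pattern, conflicts = call_pattern(table, reg, mode, tau)
        if conflicts:
            raise DecodingError(
                f"well {well}: register {rid} has conflicting strand evidence "
                f"at site(s) {conflicts}"
            )
        patterns[rid] = pattern
    stats["evidence"] = table
    return patterns, stats


def decode_run(
    well_batches: dict,
    panel: RegisterPanel,
    layout: PlateLayout,
    tau: int = DEFAULT_TAU,
    tol: int = DEFAULT_TOL,
) -> tuple:
    """Full inverse of encode -> simulate: recover the payload bytes.

    ``well_batches`` maps well names to :class:`~punchcard.channel.ReadPairBatch`
    objects (one sequencing library per well).  Returns ``(payload, report)``.
    """
    registers = {r.id: r for r in panel.registers}
    index = ReferenceIndex(registers)
    decoded_wells = {}
    report = {"wells": {}, "mode": layout.mode}
    for name, truth_patterns in layout.wells.items():
        if name not in well_batches:
            raise DecodingError(f"well {name}: no reads provided")
        want = {p.register_id: registers[p.register_id] for p in truth_patterns}
        patterns, stats = decode_well(
            well_batches[name], want, layout.mode, tau, tol, index=index, well=name
        )
        decoded_wells[name] = [patterns[p.register_id] for p in truth_patterns]
        report["wells"][name] = stats
    decoded_layout = PlateLayout(
        decoded_wells, layout.mode, layout.block_bits, layout.payload_length, layout.padding
    )
    payload = bytes_from_blocks(collect_layout(decoded_layout, panel))
    report["payload_length"] = layout.payload_length
    return payload, report


def evidence_report_rows(report: dict) -> list:
    """Flatten a decode report into rows for a TSV evidence table."""
    rows = []
    for well, stats in report["wells"].items():
        table = stats["evidence"]
        for rid, sites in table.sites.items():
            for ordinal, counts in sites.items():
                rows.append(
                    {
                        "well": well,
                        "register": rid,
                        "site": ordinal,
                        "sense_boundaries": counts[SENSE],
                        "antisense_boundaries": counts[ANTISENSE],
                    }
                )
    return rows
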