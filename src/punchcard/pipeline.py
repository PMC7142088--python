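"""End-to-end orchestration: configuration and the write->read roundtrip.

`RunConfig` gathers every tunable of the platform with defaults matching
the storage scheme's stated operating point (450 bp registers, 16-nt
guides, GC 20-60%, Hamming >= 8, spacing >= 25 bp, 250-cycle paired-end
reads, +-1 nt size tolerance, 1-read evidence threshold).  The config is
serialized into every output for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

from . import channel, codec, design, readout, seqcore


@dataclass
class RunConfig:
    register_length: int = 450
    n_registers: int = 1
    sites_per_register: tuple = (10,)
    min_spacing: int = design.MIN_SPACING
    min_hamming: int = design.MIN_HAMMING
    gc_bounds: tuple = design.GC_BOUNDS
    max_g_run: int = design.MAX_G_RUN
    similarity_threshold: float = 0.50
    end_margin: int = design.DEFAULT_END_MARGIN
    mode: str = "binary"
    read_len: int = channel.DEFAULT_READ_LEN
    coverage: int = 5
    err_rate: float = 0.0
    tol: int = readout.DEFAULT_TOL
    tau: int = readout.DEFAULT_TAU
    dissociation_threshold: int = channel.DEFAULT_DISSOCIATION_NT
    genome_length: int = 20_000
    genome_gc: float = 0.5
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=list, indent=1)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def build_panel(config: RunConfig):
    genome = seqcore.make_genome(config.genome_length, config.genome_gc, config.seed)
    panel = design.design_panel(
        genome.sequence,
        count=config.n_registers,
        length=config.register_length,
        per_register_sites=list(config.sites_per_register),
        similarity_threshold=config.similarity_threshold,
        seed=config.seed,
        two_sided=(config.mode == "ternary"),
        min_spacing=config.min_spacing,
        min_hamming=config.min_hamming,
        end_margin=config.end_margin,
    )
    return genome, panel


def simulate_layout(layout: codec.PlateLayout, panel, config: RunConfig) -> dict:
    """One sequencing library (read batch) per well."""
    registers = {r.id: r for r in panel.registers}
    refs = {rid: reg.sequence for rid, reg in registers.items()}
    batches = {}
    for w, (name, patterns) in enumerate(layout.wells.items()):
        frag_sets = []
        for pattern in patterns:
            duplex = channel.apply_pattern(registers[pattern.register_id], pattern)
            frag_sets.append(channel.denature(duplex))
        pooled = channel.pool(*frag_sets)
        batches[name] = channel.sim_reads(
            pooled,
            refs,
            coverage=config.coverage,
            read_len=config.read_len,
            err_rate=config.err_rate,
            seed=config.seed * 100_003 + w,
        )
    return batches


def roundtrip(payload: bytes, config: RunConfig | None = None) -> tuple:
    """fixture -> design -> encode -> simulate -> decode; returns (bytes, report).

    The report carries per-stage counters and the achieved bit accuracy; a
    failure in any stage raises :class:`StageError` naming the stage.
    """
    config = config or RunConfig()
    try:
        genome, panel = build_panel(config)
    except Exception as exc:
        raise StageError(f"design: {exc}") from exc
    if not payload:
        return b"", {"bit_accuracy": 1.0, "bits": 0, "config": dataclasses.asdict(config)}
    try:
        layout = codec.encode_payload(payload, panel, mode=config.mode)
    except Exception as exc:
        raise StageError(f"encode: {exc}") from exc
    try:
        batches = simulate_layout(layout, panel, config)
    except Exception as exc:
        raise StageError(f"simulate: {exc}") from exc
    try:
        recovered, report = readout.decode_run(
            batches, panel, layout, tau=config.tau, tol=config.tol
        )
    except Exception as exc:
        raise StageError(f"decode: {exc}") from exc
    bits_in = codec.bits_from_bytes(payload)
    bits_out = codec.bits_from_bytes(recovered)
    matches = sum(a == b for a, b in zip(bits_in, bits_out))
    report["bit_accuracy"] = matches / len(bits_in)
    report["bits"] = len(bits_in)
    report["config"] = dataclasses.asdict(config)
    return recovered, report
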