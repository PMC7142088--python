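"""Payload <-> nick-pattern codecs: bit blocking, binary positional coding,
sense/antisense ternary coding, and microplate layout.

Bit order is MSB-first within each byte; base-3 digits are emitted
most-significant-first.  Both orders are presentation-invariant once fixed
and are recorded in the design-file header.
"""

from __future__ import annotations

from dataclasses import dataclass

BLOCK_WIDTHS = (10, 32, 50)
PLATE_ROWS = "ABCDEFGHIJKLMNOP"  # 384-well plate, row-major A1..P24
PLATE_COLS = 24


@dataclass(frozen=True)
class NickPattern:
    """Per-site write symbols for one register.

    Binary mode: 1 = nick (on the writable strand), 0 = no nick.
    Ternary mode: 1 = sense-strand nick, 2 = antisense-strand nick, 0 = none.
    """

    register_id: str
    symbols: tuple
    mode: str = "binary"

    def __post_init__(self) -> None:
        allowed = {0, 1} if self.mode == "binary" else {0, 1, 2}
        if self.mode not in ("binary", "ternary"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not set(self.symbols) <= allowed:
            raise ValueError(f"symbols {self.symbols} illegal in {self.mode} mode")

    @property
    def nicked_ordinals(self) -> list:
        return [i + 1 for i, s in enumerate(self.symbols) if s != 0]


@dataclass
class PayloadBlockStream:
    blocks: list  # list of tuples of bits, each of width block_bits
    block_bits: int
    payload_length: int  # bytes
    padding: int  # zero bits appended to the final block


@dataclass
class PlateLayout:
    """Row-major well map; each well holds one block's patterns in panel order."""

    wells: dict  # well name -> list[NickPattern]
    mode: str
    block_bits: int
    payload_length: int
    padding: int

    @property
    def well_names(self) -> list:
        return list(self.wells)


def well_name(index: int) -> str:
    if not 0 <= index < len(PLATE_ROWS) * PLATE_COLS:
        raise ValueError(f"well index {index} outside a 384-well plate")
    return f"{PLATE_ROWS[index // PLATE_COLS]}{index % PLATE_COLS + 1}"


# ---------------------------------------------------------------------------
# Blocking
# ---------------------------------------------------------------------------

def bits_from_bytes(payload: bytes) -> list:
    return [(byte >> (7 - i)) & 1 for byte in payload for i in range(8)]


def bytes_from_bits(bits, n_bytes: int) -> bytes:
    if len(bits) < 8 * n_bytes:
        raise ValueError("not enough bits for the declared payload length")
    out = bytearray()
    for i in range(n_bytes):
        byte = 0
        for b in bits[8 * i : 8 * i + 8]:
            byte = (byte << 1) | b
        out.append(byte)
    return bytes(out)


def blocks_from_bytes(payload: bytes, m: int) -> PayloadBlockStream:
    """Parse a payload into m-bit blocks, zero-padding the final block."""
    if m < 1:
        raise ValueError("block width must be positive")
    bits = bits_from_bytes(payload)
    padding = (-len(bits)) % m
    bits.extend([0] * padding)
    blocks = [tuple(bits[i : i + m]) for i in range(0, len(bits), m)]
    return PayloadBlockStream(blocks, m, len(payload), padding)


def bytes_from_blocks(stream: PayloadBlockStream) -> bytes:
    bits = [b for block in stream.blocks for b in block]
    return bytes_from_bits(bits, stream.payload_length)


def bits_from_text(text: str, bits_per_char: int = 7) -> list:
    """ASCII text as a flat bit list (MSB-first per character)."""
    bits = []
    for ch in text:
        code = ord(ch)
        if code >= 1 << bits_per_char:
            raise ValueError(f"character {ch!r} exceeds {bits_per_char}-bit ASCII")
        bits.extend((code >> (bits_per_char - 1 - i)) & 1 for i in range(bits_per_char))
    return bits


# ---------------------------------------------------------------------------
# Binary positional coding
# ---------------------------------------------------------------------------

def encode_block(bits, register_id: str = "R0") -> NickPattern:
    """Bits map one-to-one onto sites: 1 = nick, 0 = ground state (no action)."""
    if not set(bits) <= {0, 1}:
        raise ValueError("binary block may contain only 0/1")
    return NickPattern(register_id, tuple(bits), "binary")


def decode_block(pattern: NickPattern) -> tuple:
    if pattern.mode != "binary":
        raise ValueError("decode_block expects a binary pattern")
    return pattern.symbols


def positional_code(pattern: NickPattern) -> str:
    """Human-readable positional code: nicked site ordinals.

    Compact digit string (e.g. ``"238"``) when every nicked ordinal is a
    single digit; canonical comma-separated form otherwise; ``"-"`` for the
    all-zero ground state.  Presentation only — the pattern is authoritative.
    """
    if pattern.mode != "binary":
        raise ValueError("positional code is defined for binary patterns")
    ordinals = pattern.nicked_ordinals
    if not ordinals:
        return "-"
    if ordinals[-1] <= 9:
        return "".join(str(o) for o in ordinals)
    return ",".join(str(o) for o in ordinals)


# ---------------------------------------------------------------------------
# Ternary (sense/antisense) coding — log2(3) ~ 1.58 bits per site
# ---------------------------------------------------------------------------

def ternary_capacity_bits(n_sites: int) -> int:
    """Whole bits storable on n two-sided sites: floor(n * log2 3)."""
    return (3**n_sites).bit_length() - 1


def encode_ternary(bits, n_trits: int = 32) -> tuple:
    """Pack a bit block into base-3 digits, most-significant digit first."""
    if len(bits) > ternary_capacity_bits(n_trits):
        raise ValueError(
            f"{len(bits)} bits exceed the capacity of {n_trits} trits "
            f"({ternary_capacity_bits(n_trits)} bits)"
        )
    value = 0
    for b in bits:
        value = (value << 1) | b
    trits = []
    for _ in range(n_trits):
        value, digit = divmod(value, 3)
        trits.append(digit)
    return tuple(reversed(trits))


def decode_ternary(trits, n_bits: int) -> tuple:
    value = 0
    for t in trits:
        if t not in (0, 1, 2):
            raise ValueError(f"illegal trit {t!r}")
        value = value * 3 + t
    if value >= 1 << n_bits:
        raise ValueError("trit value exceeds the declared bit width")
    return tuple((value >> (n_bits - 1 - i)) & 1 for i in range(n_bits))


def ternary_pattern(trits, register) -> NickPattern:
    """Per-site strand assignment: 1 -> sense nick, 2 -> antisense, 0 -> none."""
    if not register.two_sided:
        raise ValueError(
            f"register {register.id} is not designed for two-sided nicking"
        )
    if len(trits) != register.n_sites:
        raise ValueError("trit vector width must equal the register site count")
    return NickPattern(register.id, tuple(trits), "ternary")


# ---------------------------------------------------------------------------
# Plate layout
# ---------------------------------------------------------------------------

def _split_symbols(symbols, site_counts) -> list:
    if sum(site_counts) != len(symbols):
        raise ValueError(
            f"block width {len(symbols)} does not match panel sites {site_counts}"
        )
    out, pos = [], 0
    for n in site_counts:
        out.append(tuple(symbols[pos : pos + n]))
        pos += n
    return out


def layout_blocks(stream: PayloadBlockStream, panel, mode: str = "binary") -> PlateLayout:
    """Place blocks into wells A1, A2, ... row-major, one block per well.

    A block wider than a single register is split across the panel's
    registers in genome order (the registers' native order carries the bit
    order).  In ternary mode the block's bits are first packed into trits
    sized to the panel's total site count.
    """
    site_counts = panel.site_counts
    total_sites = sum(site_counts)
    capacity = len(PLATE_ROWS) * PLATE_COLS
    if len(stream.blocks) > capacity:
        raise ValueError(
            f"{len(stream.blocks)} blocks need {len(stream.blocks)} wells; "
            f"plate holds {capacity}"
        )
    wells = {}
    for k, block in enumerate(stream.blocks):
        if mode == "binary":
            symbols = block
        elif mode == "ternary":
            symbols = encode_ternary(block, total_sites)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        parts = _split_symbols(symbols, site_counts)
        patterns = []
        for reg, part in zip(panel.registers, parts):
            if mode == "binary":
                patterns.append(NickPattern(reg.id, part, "binary"))
            else:
                patterns.append(ternary_pattern(part, reg))
        wells[well_name(k)] = patterns
    return PlateLayout(wells, mode, stream.block_bits, stream.payload_length, stream.padding)


def collect_layout(layout: PlateLayout, panel) -> PayloadBlockStream:
    """Inverse of :func:`layout_blocks`; round-trip identity."""
    total_sites = sum(panel.site_counts)
    blocks = []
    for k, name in enumerate(layout.wells):
        if name != well_name(k):
            raise ValueError(f"well {name} out of row-major order")
        symbols = tuple(
            s for pattern in layout.wells[name] for s in pattern.symbols
        )
        if layout.mode == "binary":
            blocks.append(symbols)
        else:
            blocks.append(decode_ternary(symbols, layout.block_bits))
    return PayloadBlockStream(blocks, layout.block_bits, layout.payload_length, layout.padding)


def encode_payload(payload: bytes, panel, mode: str = "binary", block_bits: int | None = None) -> PlateLayout:
    """Payload bytes -> plate layout in one step."""
    total_sites = sum(panel.site_counts)
    if block_bits is None:
        block_bits = total_sites if mode == "binary" else ternary_capacity_bits(total_sites)
    stream = blocks_from_bytes(payload, block_bits)
    return layout_blocks(stream, panel, mode)


def decode_payload(layout: PlateLayout, panel) -> bytes:
    return bytes_from_blocks(collect_layout(layout, panel))


# --- layout serialization ---------------------------------------------------

def layout_to_dict(layout: PlateLayout) -> dict:
    return {
        "format": "punchcard-layout/1",
        "mode": layout.mode,
        "block_bits": layout.block_bits,
        "payload_length": layout.payload_length,
        "padding": layout.padding,
        "wells": {
            name: [
                {"register_id": p.register_id, "symbols": list(p.symbols), "mode": p.mode}
                for p in patterns
            ]
            for name, patterns in layout.wells.items()
        },
    }


def layout_from_dict(d: dict) -> PlateLayout:
    wells = {
        name: [
            NickPattern(p["register_id"], tuple(p["symbols"]), p["mode"])
            for p in patterns
        ]
        for name, patterns in d["wells"].items()
    }
    return PlateLayout(wells, d["mode"], d["block_bits"], d["payload_length"], d["padding"])
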