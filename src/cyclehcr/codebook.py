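"""Split L+R barcode codebooks for multicycle, multichannel HCR readout.

A target's identity is the combination (channel, left readout index, right
readout index); signal amplification fires only when the matched left and
right readout probes are both present, so the per-channel address space is
``n_left * n_right`` and the total capacity is ``n_left * n_right *
n_channels``.  Targets are read out over imaging cycles, one target per
channel per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Fluorescence channels (nm) carrying the three orthogonal HCR initiators.
CHANNELS: tuple[int, ...] = (488, 561, 640)


class CodebookError(ValueError):
    """Invalid codebook construction or parameters."""


class CapacityError(CodebookError):
    """More targets requested than the barcode space can encode."""


@dataclass(frozen=True)
class Barcode:
    """One target's readout address: channel, cycle, and L/R readout indices."""

    channel: int
    cycle: int
    left_index: int
    right_index: int

    def __post_init__(self) -> None:
        if self.cycle < 1:
            raise CodebookError(f"cycle must be >= 1, got {self.cycle}")
        if self.left_index < 1 or self.right_index < 1:
            raise CodebookError("left/right indices are 1-based and must be >= 1")


@dataclass(frozen=True)
class CycleSchedule:
    """Channel-first assignment of targets to (cycle, channel) slots."""

    n_cycles: int
    per_cycle: tuple[tuple[int, int, str], ...]  # (cycle, channel, target)

    def targets_in_cycle(self, cycle: int) -> list[str]:
        return [t for c, _, t in self.per_cycle if c == cycle]


@dataclass
class Codebook:
    """Mapping target name -> :class:`Barcode`, with non-targeting controls.

    Non-targeting entries are barcode combinations with no matching primary
    probe; any spot decoded to them is a false positive, which is what makes
    them usable as a detection-noise floor downstream.
    """

    entries: dict[str, Barcode]
    n_left: int = 30
    n_right: int = 30
    channels: tuple[int, ...] = CHANNELS
    non_targeting: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.non_targeting = frozenset(self.non_targeting)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        seen_slot: set[tuple[int, int]] = set()
        seen_triple: set[tuple[int, int, int]] = set()
        for name, bc in self.entries.items():
            if bc.channel not in self.channels:
                raise CodebookError(f"{name}: channel {bc.channel} not in {self.channels}")
            if not (1 <= bc.left_index <= self.n_left):
                raise CodebookError(f"{name}: left_index {bc.left_index} out of [1, {self.n_left}]")
            if not (1 <= bc.right_index <= self.n_right):
                raise CodebookError(f"{name}: right_index {bc.right_index} out of [1, {self.n_right}]")
            slot = (bc.channel, bc.cycle)
            if slot in seen_slot:
                raise CodebookError(f"duplicate (channel, cycle) slot {slot}")
            seen_slot.add(slot)
            triple = (bc.channel, bc.left_index, bc.right_index)
            if triple in seen_triple:
                raise CodebookError(f"duplicate (channel, L, R) triple {triple}")
            seen_triple.add(triple)
        if len(self.entries) > capacity(self.n_left, self.n_right, len(self.channels)):
            raise CapacityError("more entries than barcode capacity")
        missing = self.non_targeting - set(self.entries)
        if missing:
            raise CodebookError(f"non-targeting names not in entries: {sorted(missing)}")

    # -- conveniences -------------------------------------------------------
    @property
    def n_cycles(self) -> int:
        return max((bc.cycle for bc in self.entries.values()), default=0)

    @property
    def targets(self) -> list[str]:
        return [n for n in self.entries if n not in self.non_targeting]

    @property
    def controls(self) -> list[str]:
        return [n for n in self.entries if n in self.non_targeting]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "target": name,
                "channel": bc.channel,
                "cycle": bc.cycle,
                "left_index": bc.left_index,
                "right_index": bc.right_index,
                "is_control": name in self.non_targeting,
            }
            for name, bc in self.entries.items()
        ]
        return pd.DataFrame(rows, columns=["target", "channel", "cycle", "left_index", "right_index", "is_control"])

    def write(self, path: str | Path) -> None:
        """Write tab-separated codebook (lossless round-trip with :meth:`read`)."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, n_left: int = 30, n_right: int = 30,
             channels: tuple[int, ...] = CHANNELS) -> "Codebook":
        df = pd.read_csv(path, sep="\t")
        entries = {
            str(r.target): Barcode(int(r.channel), int(r.cycle), int(r.left_index), int(r.right_index))
            for r in df.itertuples()
        }
        controls = frozenset(str(r.target) for r in df.itertuples() if bool(r.is_control))
        return cls(entries=entries, n_left=n_left, n_right=n_right,
                   channels=channels, non_targeting=controls)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def capacity(n_left: int, n_right: int, n_channels: int) -> int:
    """Number of distinct targets encodable with the given readout-probe sets.

    With 30 left and 30 right probes a single channel encodes 900 barcodes;
    three channels encode 2,700 targets.
    """
    for name, v in (("n_left", n_left), ("n_right", n_right), ("n_channels", n_channels)):
        if int(v) != v or v < 0:
            raise CodebookError(f"{name} must be a non-negative integer, got {v!r}")
    return int(n_left) * int(n_right) * int(n_channels)


def schedule_cycles(targets: Sequence[str], n_channels: int = 3,
                    channels: Sequence[int] | None = None) -> CycleSchedule:
    """Assign targets to (cycle, channel) slots, channel-first then cycle.

    Deterministic in the input order; the final cycle may be partially
    filled, so ``n_cycles = ceil(len(targets) / n_channels)``.
    """
    targets = list(targets)
    if not targets:
        raise CodebookError("targets must be non-empty")
    if n_channels < 1:
        raise CodebookError("n_channels must be >= 1")
    if len(set(targets)) != len(targets):
        dupes = sorted({t for t in targets if targets.count(t) > 1})
        raise CodebookError(f"duplicate target names: {dupes}")
    if channels is None:
        channels = CHANNELS[:n_channels] if n_channels <= len(CHANNELS) else tuple(range(1, n_channels + 1))
    if len(channels) != n_channels:
        raise CodebookError("channels length must equal n_channels")
    per_cycle = tuple(
        (i // n_channels + 1, channels[i % n_channels], t) for i, t in enumerate(targets)
    )
    n_cycles = -(-len(targets) // n_channels)
    return CycleSchedule(n_cycles=n_cycles, per_cycle=per_cycle)


def build_codebook(targets: Sequence[str], n_non_targeting: int = 0,
                   n_left: int = 30, n_right: int = 30,
                   channels: Sequence[int] = CHANNELS, seed: int = 0,
                   control_prefix: str = "NT") -> Codebook:
    """Assign distinct (channel, L, R) barcodes and a cycle schedule.

    Allocation draws sequentially from a seed-shuffled lattice of all
    (channel, L, R) combinations, split into per-channel queues so the
    channel-first cycle schedule stays balanced. Non-targeting controls
    prefer (L, R) combinations whose half-sites are each used by at most
    one targeting entry, and never reuse an (L, R) pair of any target.
    """
    targets = list(targets)
    channels = tuple(channels)
    if len(set(targets)) != len(targets):
        raise CodebookError("duplicate target names")
    if n_non_targeting < 0:
        raise CodebookError("n_non_targeting must be >= 0")
    n_total = len(targets) + n_non_targeting
    cap = capacity(n_left, n_right, len(channels))
    if n_total > cap:
        raise CapacityError(f"{n_total} entries exceed capacity {cap} "
                            f"({n_left}x{n_right}x{len(channels)})")
    if n_total == 0:
        return Codebook(entries={}, n_left=n_left, n_right=n_right, channels=channels)

    controls = [f"{control_prefix}{i + 1:02d}" for i in range(n_non_targeting)]
    clash = set(controls) & set(targets)
    if clash:
        raise CodebookError(f"target names collide with control names: {sorted(clash)}")

    rng = np.random.default_rng(seed)
    lattice = [(ch, l, r) for ch in channels
               for l in range(1, n_left + 1) for r in range(1, n_right + 1)]
    order = rng.permutation(len(lattice))
    queues: dict[int, list[tuple[int, int, int]]] = {ch: [] for ch in channels}
    for idx in order:
        trip = lattice[idx]
        queues[trip[0]].append(trip)

    schedule = schedule_cycles(targets + controls, n_channels=len(channels), channels=channels)
    slot_of = {t: (cyc, ch) for cyc, ch, t in schedule.per_cycle}

    entries: dict[str, Barcode] = {}
    # targets first: pop from each channel queue in schedule order
    pos = {ch: 0 for ch in channels}
    target_pairs: set[tuple[int, int]] = set()
    l_use: dict[tuple[int, int], int] = {}
    r_use: dict[tuple[int, int], int] = {}
    for name in targets:
        cyc, ch = slot_of[name]
        trip = queues[ch][pos[ch]]
        pos[ch] += 1
        entries[name] = Barcode(ch, cyc, trip[1], trip[2])
        target_pairs.add((trip[1], trip[2]))
        l_use[(ch, trip[1])] = l_use.get((ch, trip[1]), 0) + 1
        r_use[(ch, trip[2])] = r_use.get((ch, trip[2]), 0) + 1

    for name in controls:
        cyc, ch = slot_of[name]
        remaining = queues[ch][pos[ch]:]
        if not remaining:
            raise CapacityError("no barcode left for a non-targeting control")
        # prefer (L, R) pairs unused by any target, with rare half-sites;
        # degrade gracefully on small lattices where that is infeasible
        fresh = [t for t in remaining if (t[1], t[2]) not in target_pairs]
        rare = [t for t in fresh
                if l_use.get((ch, t[1]), 0) <= 1 and r_use.get((ch, t[2]), 0) <= 1]
        trip = (rare or fresh or remaining)[0]
        queues[ch].remove(trip)  # consume out of order; pos stays valid for prefix
        entries[name] = Barcode(ch, cyc, trip[1], trip[2])

    return Codebook(entries=entries, n_left=n_left, n_right=n_right,
                    channels=channels, non_targeting=frozenset(controls))


def swap_barcodes(codebook: Codebook, gene_a: str, gene_b: str) -> Codebook:
    """Exchange two genes' barcodes (the barcode-swap specificity control).

    Swapping is an involution; swapping a gene with itself is a no-op.
    """
    for g in (gene_a, gene_b):
        if g not in codebook.entries:
            raise KeyError(f"unknown gene {g!r}")
    entries = dict(codebook.entries)
    entries[gene_a], entries[gene_b] = entries[gene_b], entries[gene_a]
    return replace(codebook, entries=entries)


def decode_map(codebook_used: Codebook, codebook_decode: Codebook) -> dict[str, str]:
    """Target relabeling induced by decoding with a different codebook.

    A spot emitted under ``codebook_used`` entry ``g`` carries the physical
    barcode (channel, L, R); decoding it against ``codebook_decode`` names it
    after whatever target owns that barcode there. Barcodes absent from the
    decode codebook map to nothing (the spot would be discarded).
    """
    by_triple = {
        (bc.channel, bc.left_index, bc.right_index): name
        for name, bc in codebook_decode.entries.items()
    }
    out = {}
    for name, bc in codebook_used.entries.items():
        hit = by_triple.get((bc.channel, bc.left_index, bc.right_index))
        if hit is not None:
            out[name] = hit
    return out


def crosstalk_matrix(readout_signals, reference: float) -> np.ndarray:
    """Normalize an (L-probe x R-probe) signal matrix to the matched-pair signal.

    A clean codebook shows ~1 on matched pairs and ~0 off-diagonal; residual
    off-diagonal values measure readout bleed-through.
    """
    if not np.isfinite(reference) or reference <= 0:
        raise CodebookError(f"reference signal must be positive, got {reference!r}")
    signals = np.asarray(readout_signals, dtype=float)
    return signals / float(reference)
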