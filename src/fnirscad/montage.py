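"""Prefrontal fNIRS montage and the channel orderings the ensemble CNN consumes.

The classifier's channel-embedding layers rely on a specific stacking of the
68 measurement channels: channels are interleaved so that consecutive pairs
along the channel axis are left/right mirror images of each other, and the
34 resulting pair-units are themselves grouped into 17 adjacent pairs.  A
width-2 / stride-2 depthwise convolution applied to the stacked axis then
spans exactly one inter-hemispheric pair (first spatial layer) or two
neighbouring pair-units (second spatial layer).

The exact commercial-device layout is not hard-coded; the default montage is
a geometrically constructed left/right symmetric grid that preserves the one
property the architecture exploits (mirror pairing).  A device-specific
layout can be supplied as a CSV with columns ``channel_id,x,y,hemisphere``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MontageOrdering",
    "build_default_montage",
    "montage_from_table",
    "apply_order",
    "randomized_order",
]


@dataclass(frozen=True)
class MontageOrdering:
    """Canonical channel geometry and the derived stacking/pairing structure.

    Attributes
    ----------
    channel_ids
        Channel identifiers in acquisition (file) order.
    positions
        ``(n_channels, 2)`` scalp-plane coordinates; x < 0 is the left
        hemisphere, x > 0 the right.
    hemisphere
        ``'L'`` or ``'R'`` per channel, in acquisition order.
    stacking_order
        Permutation ``p`` such that ``data[..., p]`` interleaves each left
        channel with its mirror partner: stacked positions 2i, 2i+1 are a
        symmetric pair.
    pair_map
        34 ``(left_index, right_index)`` tuples (acquisition-order indices).
    adjacency_map
        17 groups of two adjacent pair-unit indices, partitioning the 34
        pair-units.
    """

    channel_ids: tuple[str, ...]
    positions: np.ndarray
    hemisphere: tuple[str, ...]
    stacking_order: np.ndarray
    pair_map: tuple[tuple[int, int], ...]
    adjacency_map: tuple[tuple[int, int], ...]

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def validate(self) -> None:
        """Raise ``ValueError`` if any structural invariant is violated."""
        n = self.n_channels
        if sorted(self.stacking_order.tolist()) != list(range(n)):
            raise ValueError("stacking_order is not a permutation")
        seen: set[int] = set()
        for left, right in self.pair_map:
            if self.hemisphere[left] == self.hemisphere[right]:
                raise ValueError("pair members share a hemisphere label")
            seen.update((left, right))
        if seen != set(range(n)):
            raise ValueError("pair_map does not cover every channel exactly once")
        units = sorted(u for grp in self.adjacency_map for u in grp)
        if units != list(range(n // 2)):
            raise ValueError("adjacency_map does not partition the pair-units")

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_id": self.channel_ids,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "hemisphere": self.hemisphere,
            }
        )


def _row_lengths(n_left: int, max_per_row: int = 9) -> list[int]:
    rows, remaining = [], n_left
    while remaining > 0:
        take = min(max_per_row, remaining)
        rows.append(take)
        remaining -= take
    return rows


def build_default_montage(n_channels: int = 68) -> MontageOrdering:
    """Construct the default left/right symmetric prefrontal grid.

    Half the channels are laid out row by row on the left hemisphere
    (x = -1, -2, ...), the other half mirrored on the right (x-sign flip);
    mirror pairs are found by exact x-negation.  ``n_channels`` must be a
    multiple of 4 so the 2-at-a-time spatial groupings tile exactly.
    """
    if n_channels % 4 != 0 or n_channels <= 0:
        raise ValueError(
            f"n_channels must be a positive multiple of 4, got {n_channels}"
        )
    n_left = n_channels // 2
    ids, xs, ys, hemi = [], [], [], []
    # left channels first (acquisition order), then their mirrors
    coords = []
    for y, row_len in enumerate(_row_lengths(n_left)):
        for i in range(row_len):
            coords.append((-(i + 1.0), float(y)))
    for k, (x, y) in enumerate(coords):
        ids.append(f"ch{k + 1:02d}")
        xs.append(x)
        ys.append(y)
        hemi.append("L")
    for k, (x, y) in enumerate(coords):
        ids.append(f"ch{n_left + k + 1:02d}")
        xs.append(-x)
        ys.append(y)
        hemi.append("R")
    positions = np.column_stack([xs, ys]).astype(float)

    pair_map = tuple((k, n_left + k) for k in range(n_left))
    stacking = np.empty(n_channels, dtype=np.intp)
    stacking[0::2] = [p[0] for p in pair_map]
    stacking[1::2] = [p[1] for p in pair_map]
    adjacency = tuple((2 * g, 2 * g + 1) for g in range(n_left // 2))

    m = MontageOrdering(
        channel_ids=tuple(ids),
        positions=positions,
        hemisphere=tuple(hemi),
        stacking_order=stacking,
        pair_map=pair_map,
        adjacency_map=adjacency,
    )
    m.validate()
    return m


def montage_from_table(table: pd.DataFrame) -> MontageOrdering:
    """Build a montage from a user-supplied channel table.

    The table needs columns ``channel_id, x, y, hemisphere``.  Mirror pairs
    are matched by (y, |x|); each left channel must have exactly one right
    channel at the mirrored coordinate.  Channels at x == 0 are rejected —
    a midline channel should be assigned a hemisphere and a small x offset
    toward its nearest contralateral partner before import.
    """
    required = {"channel_id", "x", "y", "hemisphere"}
    if not required.issubset(table.columns):
        raise ValueError(f"montage table needs columns {sorted(required)}")
    if (table["x"] == 0).any():
        raise ValueError("channels at x == 0 cannot be mirror-paired")
    n = len(table)
    left = table.index[table["x"] < 0].tolist()
    key = {}
    for idx in table.index[table["x"] > 0]:
        key[(round(float(table.at[idx, "y"]), 6), round(float(table.at[idx, "x"]), 6))] = idx
    pair_map = []
    for idx in sorted(left, key=lambda i: (table.at[i, "y"], -table.at[i, "x"])):
        mirror = (round(float(table.at[idx, "y"]), 6), round(-float(table.at[idx, "x"]), 6))
        if mirror not in key:
            raise ValueError(f"no mirror partner for channel {table.at[idx, 'channel_id']}")
        pair_map.append((int(idx), int(key.pop(mirror))))
    if key:
        raise ValueError("unpaired right-hemisphere channels remain")
    if len(pair_map) % 2 != 0:
        raise ValueError("number of mirror pairs must be even for adjacent grouping")
    stacking = np.empty(n, dtype=np.intp)
    stacking[0::2] = [p[0] for p in pair_map]
    stacking[1::2] = [p[1] for p in pair_map]
    m = MontageOrdering(
        channel_ids=tuple(str(c) for c in table["channel_id"]),
        positions=table[["x", "y"]].to_numpy(dtype=float),
        hemisphere=tuple(str(h) for h in table["hemisphere"]),
        stacking_order=stacking,
        pair_map=tuple(pair_map),
        adjacency_map=tuple((2 * g, 2 * g + 1) for g in range(len(pair_map) // 2)),
    )
    m.validate()
    return m


def apply_order(data: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Permute the trailing (channel) axis of ``data`` by ``order``.

    Pure column permutation: values are untouched.  Raises on a
    non-bijective ordering.
    """
    order = np.asarray(order, dtype=np.intp)
    if sorted(order.tolist()) != list(range(data.shape[-1])):
        raise ValueError("order is not a permutation of the channel axis")
    return data[..., order]


def invert_order(order: np.ndarray) -> np.ndarray:
    """Inverse permutation: ``apply_order(apply_order(x, p), invert_order(p)) == x``."""
    order = np.asarray(order, dtype=np.intp)
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    return inv


def randomized_order(seed: int, n_channels: int = 68) -> np.ndarray:
    """Seed-deterministic uniformly random channel permutation.

    Used by the C3 ablation, which feeds the proposed architecture a
    channel axis whose mirror-pair structure has been destroyed.
    """
    return np.random.default_rng(seed).permutation(n_channels)
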