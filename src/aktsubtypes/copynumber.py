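"""Broad copy-number calling from GISTIC-style q-value tracks.

A broad (arm-scale) alteration in a region is called by sampling 15 genes
evenly spaced across the region and asking whether more than half have a
q value below 0.25 (less than expected by chance after multiple-testing
correction). Subgroup-specific focal events are isolated by dropping
events significant (q < 0.25) in every subgroup. Coordinates are 0-based
half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BroadCall",
    "broad_call",
    "focal_subgroup_specific",
    "broad_frequency_table",
    "Q_SIGNIFICANT",
    "N_GENES_TESTED",
]

Q_SIGNIFICANT = 0.25
N_GENES_TESTED = 15

_TRACK_COLUMNS = ("chrom", "start", "end", "gene", "q_amp", "q_del")


def _validate_track(track: pd.DataFrame) -> None:
    missing = [c for c in _TRACK_COLUMNS if c not in track.columns]
    if missing:
        raise ValueError(f"q-value track missing columns: {missing}")
    for col in ("q_amp", "q_del"):
        q = track[col].to_numpy(dtype=float)
        if ((q < 0) | (q > 1)).any():
            raise ValueError(f"{col} values outside [0, 1]")
    if (track["start"].to_numpy() < 0).any():
        raise ValueError("negative positions")


@dataclass(frozen=True)
class BroadCall:
    region: tuple[str, int, int]
    direction: str  # "gain" or "loss"
    genes: tuple[str, ...]
    n_below: int
    called: bool
    mean_q: float

    def __post_init__(self) -> None:
        expected = self.n_below / N_GENES_TESTED > 0.5
        if self.called != expected:
            raise ValueError("called flag inconsistent with the >50% rule")


def broad_call(
    track: pd.DataFrame, region: tuple[str, int, int], direction: str = "gain"
) -> BroadCall:
    """Apply the 15-gene, >50%-below-q<0.25 broad-alteration rule.

    Genes are selected nearest (by midpoint, ties to the lower coordinate)
    to 15 evenly spaced positions spanning the region; each gene is used
    once. The mean q of the selected genes is reported for transparency,
    but the call itself is the count rule.
    """
    _validate_track(track)
    chrom, start, end = region
    if end <= start:
        raise ValueError("empty region")
    qcol = {"gain": "q_amp", "loss": "q_del"}.get(direction)
    if qcol is None:
        raise ValueError(f"direction must be 'gain' or 'loss', got {direction!r}")
    sub = track[track["chrom"] == chrom].copy()
    mids = (sub["start"].to_numpy(dtype=float) + sub["end"].to_numpy(dtype=float)) / 2.0
    inside = sub[(mids >= start) & (mids < end)]
    if len(inside) < N_GENES_TESTED:
        raise ValueError(
            f"region {chrom}:{start}-{end} contains {len(inside)} genes; "
            f"need >= {N_GENES_TESTED}"
        )
    inside = inside.sort_values("start", kind="stable").reset_index(drop=True)
    in_mids = (inside["start"].to_numpy(dtype=float) + inside["end"].to_numpy(dtype=float)) / 2.0
    positions = np.linspace(start, end, N_GENES_TESTED)
    chosen: list[int] = []
    available = set(range(len(inside)))
    for pos in positions:
        # nearest unused gene midpoint; ties resolve to the lower coordinate
        best = min(available, key=lambda i: (abs(in_mids[i] - pos), in_mids[i]))
        chosen.append(best)
        available.remove(best)
    picked = inside.iloc[sorted(chosen)]
    q = picked[qcol].to_numpy(dtype=float)
    n_below = int(np.sum(q < Q_SIGNIFICANT))
    return BroadCall(
        region=(chrom, int(start), int(end)),
        direction=direction,
        genes=tuple(picked["gene"]),
        n_below=n_below,
        called=n_below / N_GENES_TESTED > 0.5,
        mean_q=float(q.mean()),
    )


def focal_subgroup_specific(focal_tables: dict[object, pd.DataFrame]) -> pd.DataFrame:
    """Keep focal events significant in some, but not all, subgroups.

    ``focal_tables`` maps subgroup -> frame with columns ``region`` and
    ``q``. Events with q < 0.25 in every subgroup are common background
    and dropped; events with q < 0.25 in at least one subgroup are kept
    and attributed to the subgroups where they are significant.
    """
    if len(focal_tables) < 2:
        raise ValueError("need focal q tables for at least two subgroups")
    wide = None
    for lab, tbl in focal_tables.items():
        t = tbl.set_index("region")["q"].rename(lab)
        wide = t.to_frame() if wide is None else wide.join(t, how="outer")
    sig = wide < Q_SIGNIFICANT
    keep = sig.any(axis=1) & ~sig.fillna(False).all(axis=1)
    out = wide[keep].copy()
    out["subgroups"] = [
        ",".join(str(lab) for lab in wide.columns if sig.loc[region, lab])
        for region in out.index
    ]
    return out.reset_index()


def broad_frequency_table(calls: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Percentage of samples per subgroup carrying each broad call.

    ``calls`` is a boolean frame indexed by sample with one column per
    region/direction (e.g. ``chr7_gain``). Subgroups with no samples in
    ``calls`` are omitted with a warning.
    """
    rows = []
    for lab in sorted(pd.unique(labels)):
        ids = labels.index[labels == lab].intersection(calls.index)
        if len(ids) == 0:
            warnings.warn(f"subgroup {lab!r} has no samples with calls; omitted")
            continue
        sub = calls.loc[ids]
        row = {"subgroup": lab, "n": len(ids)}
        for col in calls.columns:
            row[col] = 100.0 * sub[col].mean()
        rows.append(row)
    return pd.DataFrame(rows)
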