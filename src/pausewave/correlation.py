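"""Multi-scale correlations between nucleotide composition and kinetics.

Each of the six concatenated tracks (A, C, G, T indicators, IPD, insert
counts) is Haar-decomposed once; at every dyadic scale up to ``max_scale``
the Pearson correlation is computed between the smooth coefficient
vectors and, separately, between the detail coefficient vectors of every
track pair.  Smooth coefficients of an indicator track are proportional
to the local density of that nucleotide at the scale; detail coefficients
are the change in that density.  The per-scale detail power fraction of
each track quantifies how much variation the track has at each scale and
hence how much weight a correlation at that scale carries.

Zero-variance coefficient vectors (e.g. a base absent from a whole
half-signal) have no defined correlation; these entries are reported as
missing (NaN), never coerced to 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from os import PathLike

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .kinetics import ConcatenatedTracks
from .wavelet import haar_decompose

__all__ = [
    "TRACK_LABELS",
    "ScaleCorrelationTable",
    "correlate_tracks",
    "export_table",
    "load_table",
    "render_matrix",
]

TRACK_LABELS = ("A", "C", "G", "T", "IPD", "inserts")


@dataclass
class ScaleCorrelationTable:
    """Pairwise per-scale correlations plus per-track power fractions.

    ``correlations`` has one row per unordered track pair (including
    self-pairs) per scale, columns ``track_a, track_b, scale, r_smooth,
    r_detail``.  ``power`` has one row per track per scale; fractions for
    a track sum to 1 over the scales actually computed.
    """

    scales: list[int]
    correlations: pd.DataFrame = field(repr=False)
    power: pd.DataFrame = field(repr=False)

    def r(self, track_a: str, track_b: str, scale: int) -> tuple[float, float]:
        """(r_smooth, r_detail) for a pair at a scale; symmetric in the pair."""
        a, b = sorted((track_a, track_b))
        rows = self.correlations
        hit = rows[
            (rows.track_a == a) & (rows.track_b == b) & (rows.scale == scale)
        ]
        if hit.empty:
            raise KeyError(f"no entry for ({track_a}, {track_b}) at scale {scale}")
        return float(hit.r_smooth.iloc[0]), float(hit.r_detail.iloc[0])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson r; NaN when either vector is degenerate (zero variance)."""
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0.0 or sy == 0.0:
        return np.nan
    return float(np.sum(xc * yc) / (sx * sy))


def _mask_for_scale(length: int, scale: int, boundaries: list[int]) -> np.ndarray:
    """True for decimated coefficient blocks that do not span a read boundary."""
    n = length // scale
    keep = np.ones(n, dtype=bool)
    for b in boundaries:
        if b % scale != 0:  # boundary interior to block b // scale
            k = b // scale
            if k < n:
                keep[k] = False
    return keep


def correlate_tracks(
    tracks: ConcatenatedTracks,
    max_scale: int = 2048,
    mask_boundaries: bool = False,
    log_ipd: bool = False,
) -> ScaleCorrelationTable:
    """Build the full per-scale correlation/power table from six tracks.

    Parameters
    ----------
    tracks
        Concatenated power-of-two-length track vectors.
    max_scale
        Largest scale (region width) reported; must be a power of two and
        is additionally capped at half the track length so every
        correlation has at least two coefficient pairs.
    mask_boundaries
        If True, coefficients whose block spans a read boundary are
        excluded (sensitivity analysis).  Off by default: the handful of
        boundary-spanning coefficients in long-read data is harmless.
    log_ipd
        Correlate log1p(IPD) instead of raw seconds.  Extension, off by
        default; raw seconds are the canonical analysis.
    """
    if max_scale < 2 or (max_scale & (max_scale - 1)) != 0:
        raise ValidationError(f"max_scale must be a power of two >= 2, got {max_scale}")
    length = tracks.length
    if length < 2 * max_scale:
        raise ValidationError(
            f"track length {length} is below 2*max_scale = {2 * max_scale}; "
            f"not enough coefficients at the coarsest scale"
        )

    data = {label: tracks.track(label).astype(np.float64) for label in TRACK_LABELS}
    if log_ipd:
        data["IPD"] = np.log1p(data["IPD"])
    decs = {label: haar_decompose(vec) for label, vec in data.items()}
    scales = [w for w in decs["IPD"].scales if w <= max_scale]

    corr_rows = []
    for a, b in itertools.combinations_with_replacement(TRACK_LABELS, 2):
        a, b = sorted((a, b))
        for w in scales:
            keep = (
                _mask_for_scale(length, w, tracks.read_boundaries)
                if mask_boundaries
                else slice(None)
            )
            corr_rows.append(
                {
                    "track_a": a,
                    "track_b": b,
                    "scale": w,
                    "r_smooth": _pearson(decs[a].smooth[w][keep], decs[b].smooth[w][keep]),
                    "r_detail": _pearson(decs[a].detail[w][keep], decs[b].detail[w][keep]),
                }
            )

    # Detail power restricted (and normalized) to the scales in the table,
    # so each track's fractions sum to 1 over the rows actually reported.
    power_rows = []
    for label in TRACK_LABELS:
        energies = np.array([np.sum(decs[label].detail[w] ** 2) for w in scales])
        total = energies.sum()
        fracs = energies / total if total > 0 else np.full(len(scales), np.nan)
        for w, f in zip(scales, fracs):
            power_rows.append({"track": label, "scale": w, "power": f})

    return ScaleCorrelationTable(
        scales=scales,
        correlations=pd.DataFrame(corr_rows),
        power=pd.DataFrame(power_rows),
    )


def export_table(table: ScaleCorrelationTable, tsv: str | PathLike) -> None:
    """Write the table to one TSV; missing r values become empty fields.

    Rows with ``record=correlation`` carry the pair correlations; rows
    with ``record=power`` carry per-track power fractions.
    """
    corr = table.correlations.copy()
    corr.insert(0, "record", "correlation")
    corr["track"] = ""
    corr["power"] = np.nan
    pw = table.power.copy()
    pw.insert(0, "record", "power")
    pw["track_a"] = ""
    pw["track_b"] = ""
    pw["r_smooth"] = np.nan
    pw["r_detail"] = np.nan
    cols = ["record", "track_a", "track_b", "track", "scale", "r_smooth", "r_detail", "power"]
    out = pd.concat([corr[cols], pw[cols]], ignore_index=True)
    out.to_csv(tsv, sep="\t", index=False, float_format="%.6g", na_rep="")


def load_table(tsv: str | PathLike) -> ScaleCorrelationTable:
    """Inverse of :func:`export_table`."""
    df = pd.read_csv(tsv, sep="\t", keep_default_na=True)
    corr = (
        df[df.record == "correlation"][["track_a", "track_b", "scale", "r_smooth", "r_detail"]]
        .reset_index(drop=True)
        .astype({"scale": int})
    )
    power = (
        df[df.record == "power"][["track", "scale", "power"]]
        .reset_index(drop=True)
        .astype({"scale": int})
    )
    return ScaleCorrelationTable(
        scales=sorted(corr.scale.unique()), correlations=corr, power=power
    )


def render_matrix(table: ScaleCorrelationTable, path: str | PathLike) -> None:
    """Matrix figure: smooth r above the diagonal, detail r below, power on it.

    Each off-diagonal cell shows the correlation of one track pair as bars
    over scale, red for positive and blue for negative; diagonal cells
    show the track's per-scale detail power.  Format follows the file
    extension.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(TRACK_LABELS)
    scales = table.scales
    xs = np.arange(len(scales))
    fig, axes = plt.subplots(k, k, figsize=(2.0 * k, 2.0 * k), sharex=True)
    for i, a in enumerate(TRACK_LABELS):
        for j, b in enumerate(TRACK_LABELS):
            ax = axes[i, j]
            if i == j:
                vals = table.power[table.power.track == a].sort_values("scale").power.values
                ax.bar(xs, vals, color="0.4")
                ax.set_ylim(0, 1)
            else:
                lo, hi = sorted((a, b))
                rows = (
                    table.correlations[
                        (table.correlations.track_a == lo) & (table.correlations.track_b == hi)
                    ]
                    .sort_values("scale")
                )
                vals = rows.r_smooth.values if i < j else rows.r_detail.values
                colors = ["red" if v > 0 else "blue" for v in np.nan_to_num(vals)]
                ax.bar(xs, vals, color=colors)
                ax.set_ylim(-1, 1)
                ax.axhline(0.0, color="0.7", lw=0.5)
            if i == 0:
                ax.set_title(b, fontsize=10)
            if j == 0:
                ax.set_ylabel(a, fontsize=10)
            ax.set_xticks(xs[:: max(1, len(xs) // 4)])
            ax.set_xticklabels(
                [str(s) for s in scales][:: max(1, len(xs) // 4)], fontsize=6, rotation=90
            )
            ax.tick_params(labelsize=6)
    fig.suptitle("smooth r (upper) / detail r (lower) / detail power (diagonal)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
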