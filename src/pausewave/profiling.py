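"""Pause profiling around regex-defined sequence patterns.

Sites of a pattern — e.g. the G-quadruplex motif
``(GGG(.){1,7}GGG(.){1,7}GGG(.){1,7}GGG)`` or the Z-DNA-prone repeat
``CGCGCGCGCG`` — are located on both strands of a reference.  Around each
site a fixed window (default 128 nt) is laid out *in synthesis order* of
the site's strand, and every read synthesizing that strand contributes
its raw IPD plus its 2-nt and 4-nt causal wavelet smooths at the window
positions it covers.  Pooling all (site, read) observations per window
position yields count, mean and upper quantiles (default 90%/95%) per
position and track: the pause signature of the pattern.

Strand handling is strict: a site only ever aggregates reads that
synthesize its own strand, so a pattern and its reverse complement probe
the two template strands of the same loci independently — the mechanism
behind the strand asymmetry of (GGC)n versus (CCG)n repeats.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from os import PathLike

import numpy as np
import pandas as pd

from .exceptions import PatternError, ValidationError
from .kinetics import KineticRead, Reference, reverse_complement
from .wavelet import causal_smooth

__all__ = [
    "PatternSite",
    "AggregatedProfile",
    "find_sites",
    "extract_profiles",
    "export_profile",
    "load_profile",
    "export_sites_bed",
    "render_profile",
    "TRACK_ORDER",
]

TRACK_ORDER = ("raw", "smooth2", "smooth4")
_SMOOTH_SCALES = {"smooth2": 2, "smooth4": 4}


@dataclass(frozen=True)
class PatternSite:
    """One pattern match, in forward 0-based half-open coordinates.

    ``matched`` is the strand-appropriate sequence: for a reverse-strand
    site it is the reverse complement of the forward slice, i.e. the
    sequence a reverse-synthesizing polymerase reads through.
    """

    reference_name: str
    start: int
    end: int
    strand: str
    matched: str


def find_sites(
    reference: Reference,
    pattern: str,
    both_strands: bool = True,
    overlapped: bool = False,
) -> list[PatternSite]:
    """Locate leftmost non-overlapping regex matches on one or both strands.

    The reverse strand is scanned independently on the reverse complement
    and hits are mapped back to forward coordinates with strand "-"; a
    palindromic pattern therefore yields paired sites on both strands.
    With ``overlapped`` the scan resumes one position after each match
    start instead of at its end (useful inside dense tandem repeats).
    """
    try:
        rx = re.compile(pattern)
    except re.error as exc:
        raise PatternError(f"invalid pattern {pattern!r}: {exc}") from exc

    def scan(seq: str) -> list[tuple[int, int, str]]:
        hits = []
        pos = 0
        while True:
            m = rx.search(seq, pos)
            if m is None or m.end() == m.start():
                break
            hits.append((m.start(), m.end(), m.group(0)))
            pos = m.start() + 1 if overlapped else m.end()
        return hits

    length = len(reference)
    sites = [
        PatternSite(reference.name, s, e, "+", txt)
        for s, e, txt in scan(reference.sequence)
    ]
    if both_strands:
        for s, e, txt in scan(reverse_complement(reference.sequence)):
            sites.append(PatternSite(reference.name, length - e, length - s, "-", txt))
    return sorted(sites, key=lambda s: (s.start, s.strand))


@dataclass
class AggregatedProfile:
    """Pooled per-window-position pause statistics across pattern sites.

    ``data`` holds one row per (position, track) with observation count,
    mean, and the requested upper quantiles (columns ``q90``/``q95`` for
    the defaults).  Window position runs 0..window-1 in synthesis order;
    the pattern starts at ``anchor``.  Smooth tracks are undefined (count
    0) where contributing reads lack the trailing context within the
    read — smoothing never crosses read ends.
    """

    window: int
    anchor: int | None
    quantile_levels: tuple[float, ...]
    n_sites: int
    n_reads: int
    data: pd.DataFrame = field(repr=False)

    @property
    def quantile_columns(self) -> list[str]:
        return [f"q{round(100 * q)}" for q in self.quantile_levels]


def _site_window_positions(site: PatternSite, window: int, anchor: int) -> np.ndarray:
    """Forward-reference position of each window index, in synthesis order."""
    p = np.arange(window)
    if site.strand == "+":
        return site.start - anchor + p
    return (site.end - 1) + anchor - p


def extract_profiles(
    sites: list[PatternSite],
    reads: list[KineticRead],
    window: int = 128,
    anchor: int | None = None,
    quantile_levels: tuple[float, ...] = (0.90, 0.95),
    min_count: int = 1,
) -> AggregatedProfile:
    """Aggregate raw and causally smoothed IPD around pattern sites.

    Each site collects reads of its own strand that overlap its window;
    a read contributes only the positions it covers (no imputation).
    Smooths are computed within each read with :func:`causal_smooth` and
    are missing at read-leading positions without full trailing context.
    Quantiles use linear interpolation of order statistics (rank
    h = (n-1)p + 1).  ``anchor`` is the window index of the pattern
    start; by default each site is centered, floor((window - len)/2).

    An empty site or read list is not an error: the profile comes back
    with all counts 0.
    """
    if sorted(quantile_levels) != list(quantile_levels) or not all(
        0.0 < q < 1.0 for q in quantile_levels
    ):
        raise ValidationError(
            f"quantile levels must be strictly increasing in (0,1), got {quantile_levels}"
        )
    for site in sites:
        if window < site.end - site.start:
            raise ValidationError(
                f"window {window} is shorter than the pattern match at "
                f"{site.start}-{site.end} ({site.end - site.start} nt)"
            )

    # Per-read causal smooths, computed once; NaN where context is missing.
    smooth_cache: dict[str, dict[str, np.ndarray]] = {}
    for read in reads:
        tracks = {"raw": read.ipd_seconds}
        for name, scale in _SMOOTH_SCALES.items():
            tracks[name] = (
                causal_smooth(read.ipd_seconds, scale).values
                if len(read) >= scale
                else np.full(len(read), np.nan)
            )
        smooth_cache[read.read_id] = tracks

    pos_chunks: dict[str, list[np.ndarray]] = {t: [] for t in TRACK_ORDER}
    val_chunks: dict[str, list[np.ndarray]] = {t: [] for t in TRACK_ORDER}
    contributing: set[str] = set()
    anchor_used: int | None = None
    for site in sites:
        a = anchor if anchor is not None else (window - (site.end - site.start)) // 2
        if anchor_used is None:
            anchor_used = a
        fpos = _site_window_positions(site, window, a)
        lo, hi = int(fpos.min()), int(fpos.max())
        for read in reads:
            if read.strand != site.strand or read.reference_name != site.reference_name:
                continue
            rs, re_ = read.reference_start, read.reference_start + len(read)
            if re_ <= lo or rs > hi:
                continue
            # window index p -> read array index t (both in synthesis order)
            if site.strand == "+":
                t_idx = fpos - rs
            else:
                t_idx = (re_ - 1) - fpos
            valid = (t_idx >= 0) & (t_idx < len(read))
            if not valid.any():
                continue
            contributing.add(read.read_id)
            p_valid = np.nonzero(valid)[0]
            t_valid = t_idx[valid]
            tracks = smooth_cache[read.read_id]
            for name in TRACK_ORDER:
                v = tracks[name][t_valid]
                ok = ~np.isnan(v)
                pos_chunks[name].append(p_valid[ok])
                val_chunks[name].append(v[ok])

    qcols = [f"q{round(100 * q)}" for q in quantile_levels]
    pooled: dict[str, list[np.ndarray]] = {}
    for name in TRACK_ORDER:
        per_pos: list[np.ndarray] = [np.empty(0)] * window
        if pos_chunks[name]:
            allpos = np.concatenate(pos_chunks[name])
            allval = np.concatenate(val_chunks[name])
            order = np.argsort(allpos, kind="stable")
            allpos, allval = allpos[order], allval[order]
            starts = np.searchsorted(allpos, np.arange(window + 1))
            per_pos = [allval[starts[p]:starts[p + 1]] for p in range(window)]
        pooled[name] = per_pos

    rows = []
    for name in TRACK_ORDER:
        for p in range(window):
            vals = pooled[name][p]
            row = {"position": p, "track": name, "count": vals.size}
            if vals.size:
                row["mean"] = float(vals.mean())
                for col, q in zip(qcols, quantile_levels):
                    row[col] = float(np.quantile(vals, q))  # linear: h=(n-1)p+1
            else:
                row["mean"] = np.nan
                for col in qcols:
                    row[col] = np.nan
            row["low_count"] = int(vals.size < min_count)
            rows.append(row)
    data = pd.DataFrame(rows, columns=["position", "track", "count", "mean", *qcols, "low_count"])
    return AggregatedProfile(
        window=window,
        anchor=anchor_used if anchor is None else anchor,
        quantile_levels=tuple(quantile_levels),
        n_sites=len(sites),
        n_reads=len(contributing),
        data=data,
    )


def export_profile(profile: AggregatedProfile, tsv: str | PathLike) -> None:
    """Write the profile table as TSV (empty fields for undefined stats)."""
    profile.data.to_csv(tsv, sep="\t", index=False, float_format="%.6g", na_rep="")


def load_profile(tsv: str | PathLike, quantile_levels: tuple[float, ...] = (0.90, 0.95)) -> AggregatedProfile:
    """Read back an exported profile TSV (counts/means/quantiles only)."""
    df = pd.read_csv(tsv, sep="\t")
    window = int(df.position.max()) + 1 if len(df) else 0
    return AggregatedProfile(
        window=window,
        anchor=None,
        quantile_levels=tuple(quantile_levels),
        n_sites=0,
        n_reads=0,
        data=df.reset_index(drop=True),
    )


def export_sites_bed(sites: list[PatternSite], path: str | PathLike) -> None:
    """BED6-style site export: ref, start, end, matched sequence, '.', strand."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.reference_name}\t{s.start}\t{s.end}\t{s.matched}\t.\t{s.strand}\n")


def render_profile(profile: AggregatedProfile, path: str | PathLike) -> None:
    """Three-panel figure: raw IPD, 2-nt smooth, 4-nt smooth.

    Mean as a line; per-position upper-quantile bars, outermost level in
    grey and the next in black (defaults: 95% grey, 90% black), the
    layout used for pause signatures.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    qcols = profile.quantile_columns
    fig, axes = plt.subplots(3, 1, figsize=(9, 8), sharex=True)
    titles = {"raw": "raw IPD", "smooth2": "2 bp smoothing", "smooth4": "4 bp smoothing"}
    for ax, name in zip(axes, TRACK_ORDER):
        sub = profile.data[profile.data.track == name]
        x = sub.position.values
        if qcols:
            outer = sub[qcols[-1]].values
            ax.vlines(x, 0, outer, color="0.6", lw=1.5, label=qcols[-1])
            if len(qcols) > 1:
                ax.vlines(x, 0, sub[qcols[-2]].values, color="black", lw=1.5, label=qcols[-2])
        ax.plot(x, sub["mean"].values, color="tab:red", lw=1.0, label="mean")
        if profile.anchor is not None:
            ax.axvline(profile.anchor, color="tab:blue", ls=":", lw=0.8)
        ax.set_ylabel("IPD (s)" if name == "raw" else "coefficient")
        ax.set_title(titles[name], fontsize=10)
    axes[0].legend(fontsize=8, loc="upper right")
    axes[-1].set_xlabel("window position (synthesis order)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
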