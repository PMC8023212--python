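"""Windowed allele-frequency profiles and candidate-region detection.

The causal locus of a recessive mutant mapped with phenotype-selected
bulks reveals itself as a plateau of mutant-pool allele frequency near 1
along the chromosome; sliding-window means of per-variant AF smooth the
profile, and the candidate region is delimited as the longest run of
consecutive windows whose mean stays at or above a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import VariantRecord, write_tsv
from .pool_af import compute_af


@dataclass
class Window:
    start: int  # 0-based half-open
    end: int
    mean_af: float | None
    n_variants: int


@dataclass
class AFProfile:
    chrom: str
    window_bp: int
    step_bp: int
    windows: list[Window]


@dataclass
class CandidateRegion:
    """Contiguous interval where the mutant-pool AF plateaus near 1.

    start/end are 1-based inclusive for reporting; peak_pos is the midpoint
    of the window with the highest mean AF inside the region.
    """

    chrom: str
    start: int
    end: int
    peak_pos: int
    peak_af: float
    n_windows: int

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def window_af_profile(
    records: list[VariantRecord],
    pool: str,
    window_bp: int,
    step_bp: int,
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, AFProfile]:
    """Sliding-window mean allele frequency per chromosome.

    Windows start at 0 and advance by ``step_bp`` until the chromosome end
    (taken from ``chrom_lengths`` when given, else the last variant
    position); a variant contributes to every window overlapping it.
    Windows without variants have a missing mean.
    """
    if not (window_bp >= step_bp > 0):
        raise ValueError("need window_bp >= step_bp > 0")
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for rec in records:
        af = compute_af(rec, pool).af
        if af is None:
            continue
        by_chrom.setdefault(rec.chrom, []).append((rec.pos, af))
    if chrom_lengths:
        for chrom in chrom_lengths:
            by_chrom.setdefault(chrom, [])
    profiles: dict[str, AFProfile] = {}
    for chrom, sites in sorted(by_chrom.items()):
        sites.sort()
        length = (
            chrom_lengths[chrom]
            if chrom_lengths and chrom in chrom_lengths
            else (sites[-1][0] if sites else 0)
        )
        windows: list[Window] = []
        start = 0
        while start < length:
            end = min(start + window_bp, length)
            # variant pos is 1-based; window [start, end) 0-based half-open
            inside = [af for pos, af in sites if start < pos <= end]
            mean = sum(inside) / len(inside) if inside else None
            windows.append(Window(start, end, mean, len(inside)))
            start += step_bp
        profiles[chrom] = AFProfile(chrom, window_bp, step_bp, windows)
    return profiles


def detect_peak_region(
    profile: AFProfile,
    af_threshold: float = 0.9,
    min_windows: int = 2,
) -> CandidateRegion | None:
    """Delimit the AF plateau as the longest qualifying window run.

    A run is a maximal stretch of consecutive windows whose mean AF is
    present and >= af_threshold; windows with no variants break runs
    (conservative bounds).  The longest run with at least ``min_windows``
    windows wins, ties going to the leftmost; the peak is the midpoint of
    the run's best window (again leftmost on ties).  Returns None when no
    run qualifies.
    """
    if not 0.5 < af_threshold <= 1.0:
        raise ValueError("af_threshold must lie in (0.5, 1]")
    runs: list[tuple[int, int]] = []  # [first, last] window indices
    current: int | None = None
    for i, w in enumerate(profile.windows):
        ok = w.mean_af is not None and w.mean_af >= af_threshold
        if ok and current is None:
            current = i
        elif not ok and current is not None:
            runs.append((current, i - 1))
            current = None
    if current is not None:
        runs.append((current, len(profile.windows) - 1))
    runs = [r for r in runs if r[1] - r[0] + 1 >= min_windows]
    if not runs:
        return None
    best_run = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    first, last = best_run
    peak_i = max(
        range(first, last + 1),
        key=lambda i: (profile.windows[i].mean_af, -i),
    )
    peak_w = profile.windows[peak_i]
    return CandidateRegion(
        chrom=profile.chrom,
        start=profile.windows[first].start + 1,
        end=profile.windows[last].end,
        peak_pos=(peak_w.start + peak_w.end) // 2,
        peak_af=float(peak_w.mean_af),
        n_windows=last - first + 1,
    )


def region_report(
    region: CandidateRegion | None,
    candidates: list[VariantRecord],
    profiles: dict[str, AFProfile],
    tsv_path: str,
    plot_path: str | None = None,
) -> list[VariantRecord]:
    """Write the region report TSV and the AF profile plot.

    The TSV lists candidates inside the region (all pools' AFs); the plot
    shows per-window mutant-pool AF with horizontal guides at 1.0 and 0.5.
    Returns the in-region candidates.
    """
    in_region = (
        [c for c in candidates if region is not None and region.contains(c.chrom, c.pos)]
        if region is not None
        else []
    )
    rows = []
    if region is not None:
        rows.append(
            {
                "chrom": region.chrom,
                "pos": region.peak_pos,
                "record": "region",
                "detail": f"{region.start}-{region.end} peak_af={region.peak_af:.3f}",
            }
        )
    for c in in_region:
        afs = {
            p: compute_af(c, p).af for p in c.samples
        }
        detail = ",".join(
            f"{p}={'NA' if a is None else format(a, '.3f')}" for p, a in afs.items()
        )
        rows.append({"chrom": c.chrom, "pos": c.pos, "record": "candidate", "detail": detail})
    write_tsv(rows, ["chrom", "pos", "record", "detail"], tsv_path)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(
            1, max(len(profiles), 1), figsize=(5 * max(len(profiles), 1), 3.2),
            squeeze=False,
        )
        for ax, (chrom, profile) in zip(axes[0], sorted(profiles.items())):
            xs = [(w.start + w.end) / 2 / 1e6 for w in profile.windows]
            ys = [w.mean_af for w in profile.windows]
            ax.plot(xs, ys, ".-", ms=3, lw=0.8)
            ax.axhline(1.0, color="grey", ls="--", lw=0.8)
            ax.axhline(0.5, color="grey", ls="--", lw=0.8)
            if region is not None and region.chrom == chrom:
                ax.axvspan(region.start / 1e6, region.end / 1e6, alpha=0.2, color="tab:orange")
            ax.set_xlabel(f"{chrom} (Mb)")
            ax.set_ylabel("mutant-pool AF")
            ax.set_ylim(-0.05, 1.05)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return in_region
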