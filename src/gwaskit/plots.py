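"""Publication-style visualizations rendered from typed results.

Every number shown on a plot (lambda_GC, Pearson r, heritability, bias
and limits of agreement, histogram counts) is taken from the typed
result objects computed upstream — nothing is recomputed in this layer,
so the figures cannot drift from the exported tables.  Rendering is
deterministic for SVG output (fixed hash salt, no timestamp metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .lmm import AssociationResult
from .ml import PredictionResult
from .qc import GenotypeSummary
from .relatedness import KinshipMatrix, PCAResult, cluster_order

# alternating two-tone chromosome palette, fixed for reproducibility
_CHROM_COLORS = ("#1f77b4", "#ff7f0e")

plt.rcParams["svg.hashsalt"] = "gwaskit"


@dataclass
class PlotSpec:
    """Output settings for a single figure."""

    path: Path
    fmt: str = "svg"
    width_px: int = 1200
    height_px: int = 600
    dpi: int = 100
    significance_threshold: float | None = None  # default: Bonferroni 0.05/m

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.fmt not in ("png", "svg"):
            raise ValueError("fmt must be png or svg")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.significance_threshold is not None and not (
            0 < self.significance_threshold < 1
        ):
            raise ValueError("significance_threshold must be in (0, 1)")

    def figure(self):
        return plt.subplots(
            figsize=(self.width_px / self.dpi, self.height_px / self.dpi), dpi=self.dpi
        )

    def save(self, fig) -> Path:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(self.path, format=self.fmt, metadata=_no_date_metadata(self.fmt))
        plt.close(fig)
        return self.path


def _no_date_metadata(fmt: str):
    return {"Date": None} if fmt == "svg" else None


@dataclass
class PlotSummary:
    """Machine-checkable summary of what a figure shows."""

    n_points: int
    threshold_line_y: float | None = None
    n_above: int = 0
    extras: dict = field(default_factory=dict)


def _cumulative_positions(chrom: np.ndarray, pos: np.ndarray):
    """Genome-wide x coordinate: concatenate chromosomes in first-seen
    order with a small gap."""
    x = np.empty(len(pos), dtype=float)
    offset = 0.0
    ticks = {}
    order = list(dict.fromkeys(chrom))
    gap = max(pos.max() * 0.01, 1.0) if len(pos) else 1.0
    for c in order:
        sel = chrom == c
        p = pos[sel].astype(float)
        x[sel] = p + offset
        ticks[c] = offset + (p.min() + p.max()) / 2.0 if sel.any() else offset
        offset += p.max() + gap
    return x, ticks, order


def manhattan_plot(assoc: AssociationResult, spec: PlotSpec) -> PlotSummary:
    """Manhattan plot: -log10(p) (regression methods) or aggregated
    importance (ML methods) against cumulative genome position."""
    t = assoc.table
    if len(t) == 0:
        raise ValueError("association result is empty")
    if t["pos"].isna().any():
        bad = t.loc[t["pos"].isna(), "variant_id"].iloc[0]
        raise ValueError(f"variant {bad!r} has no position; cannot place on x axis")
    is_ml = "importance" in t.columns
    if is_ml:
        yv = t["importance"].to_numpy(dtype=float)
        finite = np.isfinite(yv)
        threshold = None
        ylab = "aggregated importance"
    else:
        p = t["p_value"].to_numpy(dtype=float)
        finite = np.isfinite(p) & (p > 0)
        yv = np.full(len(t), np.nan)
        yv[finite] = -np.log10(p[finite])
        m = int(finite.sum())
        alpha = (
            spec.significance_threshold
            if spec.significance_threshold is not None
            else 0.05 / max(m, 1)
        )
        threshold = -np.log10(alpha)
        ylab = "-log10(p)"

    chrom = t["chrom"].to_numpy(dtype=str)
    pos = t["pos"].to_numpy(dtype=float)
    x, ticks, order = _cumulative_positions(chrom[finite], pos[finite])

    fig, ax = spec.figure()
    for i, c in enumerate(order):
        sel = chrom[finite] == c
        ax.scatter(x[sel], yv[finite][sel], s=6, color=_CHROM_COLORS[i % 2], linewidths=0)
    if threshold is not None:
        ax.axhline(threshold, color="red", linestyle="--", linewidth=1)
    ax.set_xticks([ticks[c] for c in order])
    ax.set_xticklabels(order)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(ylab)
    ax.set_title(f"{assoc.method} ({assoc.n_samples} samples)")
    spec.save(fig)

    n_above = int((yv[finite] > threshold).sum()) if threshold is not None else 0
    return PlotSummary(
        n_points=int(finite.sum()), threshold_line_y=threshold, n_above=n_above
    )


def qq_plot(p_values, spec: PlotSpec, lambda_gc: float) -> PlotSummary:
    """QQ plot of observed vs expected -log10(p) with the supplied
    genomic inflation factor annotated (computed upstream)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p-value vector is empty")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    observed = -np.log10(np.sort(p))[::-1]
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    fig, ax = spec.figure()
    lim = max(expected.max(), observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", linewidth=1)
    ax.scatter(expected, observed, s=6, color=_CHROM_COLORS[0], linewidths=0)
    ax.annotate(f"$\\lambda_{{GC}}$ = {lambda_gc:.3f}", xy=(0.05, 0.9), xycoords="axes fraction")
    ax.set_xlabel("expected -log10(p)")
    ax.set_ylabel("observed -log10(p)")
    spec.save(fig)
    return PlotSummary(
        n_points=n,
        extras={
            "lambda_gc": float(lambda_gc),
            "max_observed": float(observed.max()),
            "max_expected": float(expected.max()),
        },
    )


def gp_plots(
    pred: PredictionResult, scatter_spec: PlotSpec, ba_spec: PlotSpec
) -> dict:
    """Correlation scatter (predicted vs observed, identity and
    least-squares lines, annotated r) and the Bland-Altman plot with the
    bias and limits-of-agreement lines from the prediction summary."""
    obs, prd = pred.observed, pred.predicted
    fig, ax = scatter_spec.figure()
    ax.scatter(obs, prd, s=14, color=_CHROM_COLORS[0])
    lo, hi = min(obs.min(), prd.min()), max(obs.max(), prd.max())
    pad = 0.05 * (hi - lo) if hi > lo else 1.0
    ax.plot([lo - pad, hi + pad], [lo - pad, hi + pad], color="grey", linewidth=1)
    if np.ptp(obs) > 0:
        slope, intercept = np.polyfit(obs, prd, 1)
        xs = np.array([lo - pad, hi + pad])
        ax.plot(xs, slope * xs + intercept, color="red", linewidth=1)
    ax.annotate(f"r = {pred.pearson_r:.3f}", xy=(0.05, 0.92), xycoords="axes fraction")
    ax.set_xlabel("observed phenotype")
    ax.set_ylabel("predicted phenotype")
    ax.set_title(f"{pred.method} genomic prediction")
    scatter_spec.save(fig)

    ba = pred.bland_altman
    fig, ax = ba_spec.figure()
    ax.scatter(ba.means, ba.differences, s=14, color=_CHROM_COLORS[0])
    ax.axhline(ba.bias, color="red", linewidth=1)
    ax.axhline(ba.loa_low, color="grey", linestyle="--", linewidth=1)
    ax.axhline(ba.loa_high, color="grey", linestyle="--", linewidth=1)
    ax.set_xlabel("mean of predicted and observed")
    ax.set_ylabel("predicted - observed")
    ba_spec.save(fig)

    return {
        "pearson_r": pred.pearson_r,
        "bias": ba.bias,
        "loa_low": ba.loa_low,
        "loa_high": ba.loa_high,
        "n_points": int(obs.size),
    }


def data_reports(
    output_dir,
    summary: GenotypeSummary | None = None,
    pca: PCAResult | None = None,
    kinship: KinshipMatrix | None = None,
    h2: float | None = None,
    delta_profile: tuple[np.ndarray, np.ndarray] | None = None,
    phenotype=None,
    fmt: str = "svg",
) -> dict[str, Path]:
    """Render the data-overview panels for whichever inputs are given.

    Panels: MAF / marker-density / heterozygosity histograms, PCA
    scatter, hierarchically clustered kinship heatmap, heritability bar
    (optionally with the delta profile likelihood), phenotype histogram.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def spec(name, w=800, h=600):
        return PlotSpec(out / f"{name}.{fmt}", fmt=fmt, width_px=w, height_px=h)

    if summary is not None:
        s = spec("maf_hist")
        fig, ax = s.figure()
        centers = (summary.maf_bin_edges[:-1] + summary.maf_bin_edges[1:]) / 2
        ax.bar(centers, summary.maf_hist, width=np.diff(summary.maf_bin_edges) * 0.9)
        ax.set_xlabel("minor allele frequency")
        ax.set_ylabel("variants")
        written["maf_hist"] = s.save(fig)

        s = spec("marker_density", w=1200)
        fig, ax = s.figure()
        for i, (chrom, (edges, counts)) in enumerate(sorted(summary.density.items())):
            centers = (edges[:-1] + edges[1:]) / 2e6
            ax.plot(centers, counts, label=f"chr{chrom}", color=_CHROM_COLORS[i % 2])
        ax.set_xlabel("position (Mbp)")
        ax.set_ylabel("variants per bin")
        ax.legend(fontsize=7)
        written["marker_density"] = s.save(fig)

        s = spec("heterozygosity")
        fig, ax = s.figure()
        ax.hist(summary.het_per_sample[np.isfinite(summary.het_per_sample)], bins=30)
        ax.set_xlabel("per-sample heterozygosity")
        ax.set_ylabel("samples")
        written["heterozygosity"] = s.save(fig)

    if pca is not None:
        s = spec("pca")
        fig, ax = s.figure()
        ax.scatter(pca.scores[:, 0], pca.scores[:, 1], s=10)
        ax.set_xlabel(f"PC1 ({100 * pca.variance_explained[0]:.1f}%)")
        ax.set_ylabel(
            f"PC2 ({100 * pca.variance_explained[1]:.1f}%)"
            if pca.scores.shape[1] > 1
            else ""
        )
        written["pca"] = s.save(fig)

    if kinship is not None:
        order = cluster_order(kinship)
        s = spec("kinship", w=800, h=800)
        fig, ax = s.figure()
        im = ax.imshow(kinship.values[np.ix_(order, order)], cmap="viridis")
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_title(f"kinship ({kinship.method_tag}), clustered")
        written["kinship"] = s.save(fig)
        written["kinship_order"] = order  # exposed for verification

    if h2 is not None:
        s = spec("heritability", w=500)
        fig, ax = s.figure()
        ax.bar([0], [h2], width=0.5)
        ax.set_ylim(0, 1)
        ax.set_xticks([0])
        ax.set_xticklabels(["h2"])
        ax.annotate(f"h2 = {h2:.3f}", xy=(0.35, 0.92), xycoords="axes fraction")
        if delta_profile is not None:
            ax2 = ax.inset_axes([0.55, 0.55, 0.4, 0.4])
            ax2.plot(np.log10(delta_profile[0]), delta_profile[1], linewidth=1)
            ax2.set_xlabel("log10 delta", fontsize=6)
            ax2.set_ylabel("REML loglik", fontsize=6)
            ax2.tick_params(labelsize=6)
        written["heritability"] = s.save(fig)

    if phenotype is not None:
        y = np.asarray(phenotype, dtype=float)
        s = spec("phenotype_hist")
        fig, ax = s.figure()
        ax.hist(y[np.isfinite(y)], bins=30)
        ax.set_xlabel("phenotype")
        ax.set_ylabel("samples")
        written["phenotype_hist"] = s.save(fig)

    return written
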