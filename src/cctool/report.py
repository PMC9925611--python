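"""Figures and result tables.

Diverging loading plots with bootstrap error bars (robust loadings
highlighted), composite-score scatterplots of the paired latent scores, and
normative-trajectory plots.  Every number shown in a figure is also written
to a table; figures are never the only record.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .columns import FAMILY_OF
from .normative_model import NormativeModel, assign_bins
from .plsc import PLSCResult

FAMILY_COLORS = {
    "volume": "#7f7f7f", "fa": "#1f77b4", "md": "#d62728",
    "ndi": "#2ca02c", "odi": "#9467bd", "clinical": "#ff7f0e",
}


def result_tables(result: PLSCResult) -> dict[str, pd.DataFrame]:
    """Flatten a PLSCResult into writable tables."""
    comps = pd.DataFrame({
        "component": np.arange(result.K),
        "singular_value": result.singular_values,
        "perm_p": result.perm_p if result.perm_p is not None else np.nan,
    })
    rows = []
    for side, names in (("X", result.x_names), ("Y", result.y_names)):
        loadings = getattr(result, f"loadings_{side}")
        sd = getattr(result, f"boot_sd_{side}")
        bz = getattr(result, f"boot_z_{side}")
        bp = getattr(result, f"boot_p_{side}")
        robust = getattr(result, f"robust_{side}")
        for k in range(result.K):
            for i, name in enumerate(names):
                rows.append({
                    "block": side, "component": k, "variable": name,
                    "loading": loadings[i, k],
                    "boot_sd": sd[i, k] if sd is not None else np.nan,
                    "boot_z": bz[i, k] if bz is not None else np.nan,
                    "boot_p": bp[i, k] if bp is not None else np.nan,
                    "robust": bool(robust[i, k]) if robust is not None else False,
                })
    return {"components": comps, "loadings": pd.DataFrame(rows)}


def _diverging_bars(ax, names, values, errors, robust, colors, title):
    y = np.arange(len(names))
    ax.barh(y, values, xerr=errors, color=colors,
            alpha=None, edgecolor="black",
            linewidth=[1.5 if r else 0.3 for r in robust],
            error_kw={"elinewidth": 0.8})
    for yi, r in zip(y, robust):
        if not r:
            ax.patches[yi].set_alpha(0.35)
    ax.axvline(0, color="black", linewidth=0.8)
    ax.set_yticks(y, names, fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("loading (structure coefficient)")
    ax.set_title(title, fontsize=9)


def plot_loadings(result: PLSCResult, component: int, out_dir: str | Path,
                  fmt: str = "png") -> list[Path]:
    """Diverging bar charts of clinical and structural loadings ± boot SD."""
    if not 0 <= component < result.K:
        raise ValueError(f"component {component} out of range [0, {result.K})")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    k = component
    annot = ""
    if result.perm_p is not None and result.perm_p[k] >= 0.01:
        annot = f"  (p = {result.perm_p[k]:.3f} ≥ 0.01, not significant)"
    paths = []
    for side, names, label in (("X", result.x_names, "clinical"),
                               ("Y", result.y_names, "structural")):
        loadings = getattr(result, f"loadings_{side}")[:, k]
        sd = getattr(result, f"boot_sd_{side}")
        sd = sd[:, k] if sd is not None else np.zeros_like(loadings)
        robust = getattr(result, f"robust_{side}")
        robust = robust[:, k] if robust is not None else np.zeros(len(names), bool)
        colors = [FAMILY_COLORS.get(FAMILY_OF.get(nm, "clinical"), "#ff7f0e")
                  for nm in names]
        fig, ax = plt.subplots(figsize=(6, max(2.5, 0.22 * len(names))))
        _diverging_bars(ax, names, loadings, sd, robust, colors,
                        f"Latent component {k + 1}: {label} loadings{annot}")
        fig.tight_layout()
        path = out_dir / f"loadings_lc{k + 1}_{label}.{fmt}"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths


def plot_latent_scores(result: PLSCResult, component: int,
                       out_dir: str | Path, fmt: str = "png") -> Path:
    """Scatter of clinical vs structural composite scores for one component."""
    if not 0 <= component < result.K:
        raise ValueError(f"component {component} out of range [0, {result.K})")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lx = result.latent_X[:, component]
    ly = result.latent_Y[:, component]
    r = float(np.corrcoef(lx, ly)[0, 1])
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(lx, ly, s=18, color="#1f77b4", edgecolor="white")
    ax.set_xlabel("clinical composite score")
    ax.set_ylabel("structural composite score")
    ax.set_title(f"Latent component {component + 1} (r = {r:.2f})", fontsize=9)
    fig.tight_layout()
    path = out_dir / f"latent_scores_lc{component + 1}.{fmt}"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_trajectory(norms: NormativeModel, measure: str, out_dir: str | Path,
                    fmt: str = "png") -> Path:
    """FT data, LOESS trajectory and bin norms for one structural measure."""
    if measure not in norms.loess:
        raise ValueError(f"no LOESS fit stored for {measure}")
    fit = norms.loess[measure]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    order = np.argsort(fit.x)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(fit.x, fit.y, s=16, color="#e8b320", label="full-term")
    ax.plot(fit.x[order], fit.fitted[order], color="#1f77b4",
            label=f"LOESS (span {fit.span:.2f})")
    edges = norms.bin_edges
    centers = (edges[:-1] + edges[1:]) / 2
    mu = norms.mu[measure].to_numpy()
    sigma = norms.sigma[measure].to_numpy()
    ax.errorbar(centers, mu, yerr=sigma, fmt="s", color="black",
                capsize=3, label="bin norm ± SD")
    for e in edges:
        ax.axvline(e, color="grey", linewidth=0.4, linestyle=":")
    ax.set_xlabel("age (months)")
    ax.set_ylabel(measure)
    ax.legend(fontsize=7)
    fig.tight_layout()
    path = out_dir / f"trajectory_{measure}.{fmt}"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def descriptives_table(clinical_df: pd.DataFrame) -> pd.DataFrame:
    """Group-comparison summary of the cohort's demographic traits."""
    from .cohort_stats import GroupSummary, chi_square_2x2, welch_p, welch_t_from_summary

    vpt = clinical_df[clinical_df["group"] == "VPT"]
    ft = clinical_df[clinical_df["group"] == "FT"]
    rows = []
    traits = [("age_months", "Age at assessment (months)"),
              ("ga_weeks", "Gestational age (weeks)")]
    for opt, label in (("birth_weight_g", "Birth weight (g)"),
                       ("ses", "Socio-economic risk (Largo)")):
        if opt in clinical_df.columns:
            traits.append((opt, label))
    for col, label in traits:
        s = GroupSummary(vpt[col].mean(), vpt[col].std(ddof=1), len(vpt),
                         ft[col].mean(), ft[col].std(ddof=1), len(ft))
        t, df = welch_t_from_summary(s)
        rows.append({"trait": label, "vpt_mean": s.mean1, "vpt_sd": s.sd1,
                     "ft_mean": s.mean2, "ft_sd": s.sd2,
                     "stat": t, "df": df, "p": welch_p(t, df), "test": "welch_t"})
    a = int((vpt["sex"] == "F").sum())
    b = int((vpt["sex"] == "M").sum())
    c = int((ft["sex"] == "F").sum())
    d = int((ft["sex"] == "M").sum())
    stat, df, p = chi_square_2x2(a, b, c, d)
    rows.append({"trait": "Sex (F/M)", "vpt_mean": a, "vpt_sd": b,
                 "ft_mean": c, "ft_sd": d, "stat": stat, "df": df, "p": p,
                 "test": "chi_square"})
    return pd.DataFrame(rows)
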