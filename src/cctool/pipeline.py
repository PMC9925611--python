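"""End-to-end configured runs: load/simulate -> preprocess -> normative -> PLSC -> report.

A :class:`RunConfig` fully determines a run; identical config + seed gives a
byte-identical JSON summary.  On any stage error, partial outputs of the run
are removed before the error propagates with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .data_model import load_cohort, write_cohort
from .normative_model import fit_normative_model, make_age_bins, compute_w_scores
from .plsc import run_plsc
from .preprocess import build_matrices
from .report import descriptives_table, plot_latent_scores, plot_loadings, result_tables
from .synthetic_cohort import CohortSpec, generate_cohort, planted_truth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    out_dir: str = "cctool_run"
    # input: either paths to existing CSVs, or simulate=True
    clinical_path: str | None = None
    structural_path: str | None = None
    simulate: bool = False
    simulate_spec: dict = field(default_factory=dict)
    # analysis switches
    group: str = "vpt"              # ft | vpt
    y_source: str = "measures"      # measures | wscores
    include_ses: bool = False
    n_perm: int = 1000
    n_boot: int = 500
    bin_mode: str = "study"         # study | equal
    n_bins: int = 4
    wscore_basis: str = "bins"      # bins | loess
    alpha: float = 0.01
    r_threshold: float = 0.4
    seed: int = 0
    figures: bool = True
    fig_format: str = "png"

    def validate(self) -> None:
        if self.group not in ("ft", "vpt"):
            raise ValueError(f"group must be 'ft' or 'vpt', got {self.group!r}")
        if self.y_source not in ("measures", "wscores"):
            raise ValueError(f"y_source must be 'measures' or 'wscores', got {self.y_source!r}")
        if self.group == "ft" and self.y_source == "wscores":
            raise ValueError("W-scores quantify VPT deviation from FT norms; "
                             "group='ft' with y_source='wscores' is undefined")
        if not self.simulate and (self.clinical_path is None or self.structural_path is None):
            raise ValueError("either simulate=True or both input paths are required")
        if self.n_perm < 100:
            logger.warning("n_perm = %d < 100: permutation p-values will be coarse", self.n_perm)
        if self.n_boot < 100:
            logger.warning("n_boot = %d < 100: bootstrap SDs will be noisy", self.n_boot)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis chain and write all artifacts.

    Returns the JSON-serializable run summary.  Artifacts: cohort CSVs (for
    simulated runs, plus truth.json), descriptives.csv, norms.csv and
    wscores.csv (when W-scores are involved), plsc_components.csv,
    plsc_loadings.csv, plsc_summary.json, figures, and run.log.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cctool")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "setup"
    try:
        if config.simulate:
            stage = "simulate"
            spec = CohortSpec(**{**config.simulate_spec, "seed": config.seed})
            clinical, structural = generate_cohort(spec)
            cpath, spath = write_cohort(clinical, structural, out_dir)
            written += [cpath, spath]
            truth_path = out_dir / "truth.json"
            planted_truth(spec).to_json(truth_path)
            written.append(truth_path)
        else:
            stage = "load"
            clinical, structural = load_cohort(config.clinical_path, config.structural_path)

        stage = "descriptives"
        desc = descriptives_table(clinical.df)
        desc_path = out_dir / "descriptives.csv"
        desc.to_csv(desc_path, index=False)
        written.append(desc_path)

        stage = "preprocess"
        group = config.group.upper()
        mats = build_matrices(clinical, structural, group=group,
                              include_ses=config.include_ses)

        norms = None
        if config.y_source == "wscores":
            stage = "normative"
            ft = build_matrices(clinical, structural, group="FT")
            from .data_model import StructuralTable
            import pandas as pd
            ft_struct = StructuralTable(
                pd.DataFrame(ft.Y, columns=ft.y_names).assign(subject_id=ft.row_ids)
            )
            edges = make_age_bins(config.bin_mode,
                                  age_min=float(ft.X[:, 0].min()),
                                  age_max=float(ft.X[:, 0].max()),
                                  n_bins=config.n_bins)
            norms = fit_normative_model(ft_struct, ft.X[:, 0], bin_edges=edges)
            norm_rows = []
            for b in range(norms.n_bins):
                for m in norms.mu.columns:
                    norm_rows.append({
                        "bin": b, "bin_lo": norms.bin_edges[b],
                        "bin_hi": norms.bin_edges[b + 1], "measure": m,
                        "mu": norms.mu.loc[b, m], "sigma": norms.sigma.loc[b, m],
                        "n": int(norms.n[b]),
                    })
            norms_path = out_dir / "norms.csv"
            pd.DataFrame(norm_rows).to_csv(norms_path, index=False)
            written.append(norms_path)

            vpt_struct = StructuralTable(
                pd.DataFrame(mats.Y, columns=mats.y_names).assign(subject_id=mats.row_ids)
            )
            wtable = compute_w_scores(vpt_struct, mats.X[:, 0], norms,
                                      basis=config.wscore_basis)
            w_path = out_dir / "wscores.csv"
            wtable.w.join(wtable.bin_index).to_csv(w_path)
            written.append(w_path)
            Y = wtable.w.to_numpy()
            y_names = list(wtable.w.columns)
        else:
            Y = mats.Y
            y_names = mats.y_names

        stage = "plsc"
        result = run_plsc(mats.X, Y, n_perm=config.n_perm, n_boot=config.n_boot,
                          seed=config.seed, alpha=config.alpha,
                          r_threshold=config.r_threshold,
                          x_names=mats.x_names, y_names=y_names)
        tables = result_tables(result)
        comp_path = out_dir / "plsc_components.csv"
        load_path = out_dir / "plsc_loadings.csv"
        tables["components"].to_csv(comp_path, index=False)
        tables["loadings"].to_csv(load_path, index=False)
        written += [comp_path, load_path]

        stage = "report"
        if config.figures:
            written += plot_loadings(result, 0, out_dir / "figures",
                                     fmt=config.fig_format)
            written.append(plot_latent_scores(result, 0, out_dir / "figures",
                                              fmt=config.fig_format))

        summary = {
            "package_version": __version__,
            "config": asdict(config),
            "seed": config.seed,
            "permutation_seed": result.extras["perm_seed"],
            "bootstrap_seed": result.extras["boot_seed"],
            "n_subjects": len(mats.row_ids),
            "n_components": result.K,
            "singular_values": [float(s) for s in result.singular_values],
            "perm_p": [float(p) for p in result.perm_p],
            "robust_clinical": [n for n, r in zip(result.x_names, result.robust_X[:, 0]) if r],
            "robust_structural": [n for n, r in zip(result.y_names, result.robust_Y[:, 0]) if r],
        }
        summary_path = out_dir / "plsc_summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        written.append(summary_path)
        logger.info("run complete: %d artifacts in %s", len(written), out_dir)
        return summary
    except Exception as exc:
        for path in written:
            try:
                Path(path).unlink(missing_ok=True)
            except OSError:
                pass
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
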