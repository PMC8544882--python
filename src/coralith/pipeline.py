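"""Pipeline orchestration: simulate -> derive -> summarize/compare -> regress.

Stages are pure functions of ``(config, input files)``:

* :func:`run_simulate` writes the synthetic raw-measurement bundle,
* :func:`run_derive` turns raw tables into derived skeletal, assay and
  morphometric tables,
* :func:`run_analysis` produces interspecific summaries, contrasts,
  outlier screens and the principal-component regression fits,
* :func:`run_report` renders a Markdown report from the machine-readable
  outputs (every number in the report exists in a CSV/JSON first).

Outputs are written only after a stage completes, so a failed stage leaves
no partial tables.  All data products are byte-deterministic given the same
config and seed; the per-stage run manifest additionally records a
wall-clock timestamp and is the one file excluded from byte-level
reproducibility.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assays import PIGMENTS, CoefficientMatrix, afdw_table, quantify_pigment_table
from .densitometry import derive_skeletons
from .errors import DomainError, FitError, SchemaError
from .interspecific import (
    anova_outlier_report,
    breusch_pagan,
    contrasts_frame,
    fit_oneway_anova,
    summarize_table,
    tukey_contrasts,
)
from .morphometrics import profile_table
from .pcreg import (
    MORPHOLOGY_VARIABLES,
    fit_gamma_glm,
    fit_lognormal_regression,
    gamma_cooks_distance,
    pca,
    simulate_residual_diagnostics,
    standardize,
)
from .synth import default_species_profiles, generate_raw_measurements

__all__ = ["PipelineConfig", "run_simulate", "run_derive", "run_analysis", "run_report"]

log = logging.getLogger("coralith.pipeline")

RESPONSES = ("afdw", "chl_a", "chl_b", "chl_c", "chl_d")
#: Responses entering the PC regression and their error families; chlorophyll c
#: is excluded (zero-inflated: absent from many skeletons).
REGRESSION_FAMILIES = {
    "afdw": "lognormal",
    "chl_a": "gamma-log",
    "chl_b": "gamma-log",
    "chl_d": "gamma-log",
}

_ZERO_POLICIES = ("exclude", "half_min_offset")
_CTC_MODES = ("mean_of_ratios", "pooled_means")
_WAVELENGTH_SETS = ("printed", "conventional")


@dataclass
class PipelineConfig:
    """Run configuration; loadable from YAML or JSON."""

    data_dir: str = "."
    outdir: str = "out"
    seed: int = 0
    n_per_species: int = 10
    literal_eq2: bool = False
    mad_constant: float = 1.4826
    zero_log_policy: str = "exclude"
    ctc_aggregation: str = "mean_of_ratios"
    wavelength_set: str = "printed"
    wax_density_g_cm3: float = 0.90
    coefficient_matrix_path: str | None = None
    reference_stat: str = "mean"
    n_sims_diagnostics: int = 250

    def __post_init__(self) -> None:
        if self.zero_log_policy not in _ZERO_POLICIES:
            raise SchemaError(f"zero_log_policy must be one of {_ZERO_POLICIES}")
        if self.ctc_aggregation not in _CTC_MODES:
            raise SchemaError(f"ctc_aggregation must be one of {_CTC_MODES}")
        if self.wavelength_set not in _WAVELENGTH_SETS:
            raise SchemaError(f"wavelength_set must be one of {_WAVELENGTH_SETS}")
        if self.coefficient_matrix_path is not None and not Path(
            self.coefficient_matrix_path
        ).exists():
            raise SchemaError(
                f"coefficient_matrix_path does not exist: {self.coefficient_matrix_path}"
            )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        p = Path(path)
        with open(p) as fh:
            raw = json.load(fh) if p.suffix == ".json" else yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise SchemaError(f"unknown config keys: {sorted(extra)}")
        return cls(**raw)

    def coefficient_matrix(self) -> CoefficientMatrix:
        if self.coefficient_matrix_path is not None:
            return CoefficientMatrix.from_json(self.coefficient_matrix_path)
        return CoefficientMatrix.ritchie_90_acetone(self.wavelength_set)


def _write_manifest(outdir: Path, stage: str, config: PipelineConfig, row_counts: dict,
                    warnings_seen: list) -> None:
    manifest = {
        "stage": stage,
        "software_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "row_counts": row_counts,
        "warnings": warnings_seen,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


def _read_csv(data_dir: Path, name: str, required: tuple[str, ...]) -> pd.DataFrame:
    path = data_dir / name
    if not path.exists():
        raise SchemaError(f"required input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing required column(s) {missing}")
    return df


def run_simulate(config: PipelineConfig) -> Path:
    """Write the default synthetic raw-measurement bundle into ``outdir``."""
    outdir = Path(config.outdir)
    bundle = generate_raw_measurements(
        default_species_profiles(),
        n_per_species=config.n_per_species,
        seed=config.seed,
        wax_density=config.wax_density_g_cm3,
        coefficients=config.coefficient_matrix(),
        outdir=outdir,
    )
    counts = {t: len(getattr(bundle, t)) for t in bundle._TABLES}
    log.info("simulate: wrote %s", ", ".join(f"{k}={v}" for k, v in counts.items()))
    _write_manifest(outdir, "simulate", config, counts, [])
    return outdir


def run_derive(config: PipelineConfig) -> Path:
    """Raw tables -> derived skeleton, assay and morphometric tables."""
    data_dir = Path(config.data_dir)
    outdir = Path(config.outdir)
    warnings_seen: list[str] = []

    bw = _read_csv(data_dir, "buoyant_weights.csv", ("specimen_id", "species", "wet_mass_g"))
    derived = derive_skeletons(
        bw,
        literal_eq2=config.literal_eq2,
        wax_density=config.wax_density_g_cm3,
        reference_stat=config.reference_stat,
    )
    for meta_col in ("sample_set", "pair_id"):
        if meta_col in bw.columns:
            derived = derived.merge(bw[["specimen_id", meta_col]], on="specimen_id")

    od = _read_csv(data_dir, "optical_density.csv", ("specimen_id", "wavelength_nm", "replicate", "od"))
    meta = _read_csv(data_dir, "assay_meta.csv", ("specimen_id", "extract_volume_ml"))
    meta = meta.merge(
        derived[["specimen_id", "v_bio_cm3"]].rename(columns={"v_bio_cm3": "v_bio_e_cm3"}),
        on="specimen_id",
        how="left",
    )
    if meta["v_bio_e_cm3"].isna().any():
        bad = meta.loc[meta["v_bio_e_cm3"].isna(), "specimen_id"].tolist()
        raise SchemaError(f"assay specimens without derived volumes: {bad}")
    pigments = quantify_pigment_table(od, meta, config.coefficient_matrix())
    n_clamped = int(
        sum((~pigments[f"detected_{p[-1]}"]).sum() for p in PIGMENTS)
    )
    if n_clamped:
        msg = f"{n_clamped} pigment solutions at or below zero were clamped (not detected)"
        warnings_seen.append(msg)
        log.info("derive: %s", msg)

    furnace = _read_csv(data_dir, "furnace.csv", ("specimen_id", "dried_mass_mg", "ashed_mass_mg"))
    afdw_df = afdw_table(furnace, meta)
    assay_results = pigments.merge(afdw_df, on="specimen_id").merge(
        derived[[c for c in ("specimen_id", "species", "pair_id") if c in derived.columns]],
        on="specimen_id",
    )

    corallites = _read_csv(data_dir, "corallites.csv", ("specimen_id", "corallite_index"))
    tissue = _read_csv(data_dir, "tissue.csv", ("specimen_id", "point_index", "thickness_mm"))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        morpho = profile_table(corallites, tissue, ctc_aggregation=config.ctc_aggregation)
        warnings_seen.extend(str(w.message) for w in caught)
    morpho = morpho.merge(
        derived[[c for c in ("specimen_id", "species", "pair_id") if c in derived.columns]],
        on="specimen_id",
    )

    outdir.mkdir(parents=True, exist_ok=True)
    derived.to_csv(outdir / "derived_skeletons.csv", index=False, lineterminator="\n")
    assay_results.to_csv(outdir / "assay_results.csv", index=False, lineterminator="\n")
    morpho.to_csv(outdir / "morphometrics.csv", index=False, lineterminator="\n")
    counts = {
        "derived_skeletons": len(derived),
        "assay_results": len(assay_results),
        "morphometrics": len(morpho),
    }
    log.info("derive: wrote %s", counts)
    _write_manifest(outdir, "derive", config, counts, warnings_seen)
    return outdir


def _tidy_responses(assay_results: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, r in assay_results.iterrows():
        for resp in RESPONSES:
            col = "afdw_mg_cm3" if resp == "afdw" else f"{resp}_ug_cm3"
            rows.append(
                {
                    "specimen_id": r["specimen_id"],
                    "species": r["species"],
                    "pair_id": r.get("pair_id"),
                    "response_name": resp,
                    "value": float(r[col]),
                }
            )
    return pd.DataFrame(rows)


def _fit_to_dict(fit, response: str) -> dict:
    d = {
        "response": response,
        "family": fit.family,
        "coefficients": {n: float(c) for n, c in zip(fit.param_names, fit.coefficients)},
        "se": {n: float(v) for n, v in zip(fit.param_names, fit.se)},
        "t": {n: float(v) for n, v in zip(fit.param_names, fit.t)},
        "p": {n: float(v) for n, v in zip(fit.param_names, fit.p)},
        "phi": float(fit.phi),
        "alpha_shape": float(fit.alpha_shape),
        "deviance": float(fit.deviance),
        "null_deviance": float(fit.null_deviance),
        "pseudo_r2": float(fit.pseudo_r2),
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "n": int(len(fit.y)),
    }
    if fit.f_stat is not None:
        d["f_stat"] = float(fit.f_stat)
        d["f_p"] = float(fit.f_p)
    return d


def run_analysis(config: PipelineConfig) -> Path:
    """Derived tables -> summaries, contrasts, outlier screens and PC regression."""
    data_dir = Path(config.data_dir)
    outdir = Path(config.outdir)
    warnings_seen: list[str] = []

    derived = _read_csv(data_dir, "derived_skeletons.csv", ("specimen_id", "species", "v_bio_cm3"))
    assay = _read_csv(data_dir, "assay_results.csv", ("specimen_id", "species", "afdw_mg_cm3"))
    morpho = _read_csv(data_dir, "morphometrics.csv", ("specimen_id", "complexity"))
    if assay["species"].nunique() < 2:
        raise DomainError("fewer than 2 species: interspecific analysis is undefined")

    tidy = _tidy_responses(assay)
    summaries = summarize_table(tidy, consistency_constant=config.mad_constant)

    contrast_tables, test_rows, outlier_rows, refit_tables = [], [], [], []
    for resp in RESPONSES:
        sub = tidy[tidy["response_name"] == resp][["specimen_id", "species", "value"]]
        if (sub["value"] == 0).any() and config.zero_log_policy == "exclude":
            msg = (
                f"{resp}: contains exact zeros; excluded from log-scale ANOVA "
                "(zero_log_policy=exclude)"
            )
            warnings_seen.append(msg)
            log.info("analyze: %s", msg)
            continue
        policy = "half_min_offset" if config.zero_log_policy == "half_min_offset" else "error"
        report = anova_outlier_report(sub, log_transform=True, zero_policy=policy)
        afit = fit_oneway_anova(sub, log_transform=True, zero_policy=policy)
        lm, df_bp, p_bp = breusch_pagan(afit)
        test_rows.append(
            {
                "response_name": resp,
                "F": afit.F,
                "p_F": afit.p_F,
                "df_between": afit.df_between,
                "df_residual": afit.df_residual,
                "bp_lm": lm,
                "bp_df": df_bp,
                "bp_p": p_bp,
            }
        )
        ct = contrasts_frame(tukey_contrasts(afit))
        ct.insert(0, "response_name", resp)
        contrast_tables.append(ct)
        for sid, d in report.flagged:
            log.info("analyze: outlier flagged response=%s specimen=%s cooks_d=%.4f "
                     "(threshold %.4f)", resp, sid, d, report.threshold)
            outlier_rows.append(
                {
                    "response_name": resp,
                    "specimen_id": sid,
                    "cooks_d": d,
                    "threshold": report.threshold,
                }
            )
        cmp_tbl = report.comparison.copy()
        cmp_tbl.insert(0, "response_name", resp)
        refit_tables.append(cmp_tbl)

    # ---- principal-component regression on paired specimens
    morph_cols = {
        "rho_micro_g_cm3": derived.set_index("specimen_id")["rho_micro_g_cm3"],
        "porosity_fraction": derived.set_index("specimen_id")["porosity_fraction"],
    }
    morph = morpho.set_index("specimen_id").join(pd.DataFrame(morph_cols))
    morph = morph.rename(columns={"tissue_thickness_mm": "tissue_thickness_mm"})
    if "pair_id" not in morph.columns or "pair_id" not in assay.columns:
        raise SchemaError(
            "principal-component regression requires an explicit pairing key "
            "('pair_id') on both morphology and assay specimens"
        )
    X = morph.reset_index()[["specimen_id", "pair_id", *MORPHOLOGY_VARIABLES]].dropna()
    X = X.sort_values("pair_id").reset_index(drop=True)
    std = standardize(X[list(MORPHOLOGY_VARIABLES)])
    pc = pca(std)
    loadings = pd.DataFrame(
        pc.loadings,
        index=list(MORPHOLOGY_VARIABLES),
        columns=[f"PC{i+1}" for i in range(pc.loadings.shape[1])],
    )
    variance = pd.DataFrame(
        {
            "component": loadings.columns,
            "eigenvalue": pc.eigenvalues,
            "variance_fraction": pc.variance_fraction,
        }
    )
    scores = pd.DataFrame(
        pc.scores[:, :2], columns=["PC1", "PC2"]
    )
    scores.insert(0, "pair_id", X["pair_id"].to_numpy())
    scores.insert(0, "specimen_id", X["specimen_id"].to_numpy())

    assay_by_pair = assay.set_index("pair_id")
    fits, fit_dicts = {}, []
    unconverged = []
    for i, (resp, family) in enumerate(sorted(REGRESSION_FAMILIES.items())):
        col = "afdw_mg_cm3" if resp == "afdw" else f"{resp}_ug_cm3"
        joined = scores.join(assay_by_pair[[col]], on="pair_id").dropna(subset=[col])
        y = joined[col].to_numpy(dtype=float)
        keep = y > 0
        if (~keep).any():
            msg = (
                f"{resp}: {int((~keep).sum())} zero (non-detected) responses dropped "
                "from the regression"
            )
            warnings_seen.append(msg)
            log.info("analyze: %s", msg)
        y = y[keep]
        s = joined[["PC1", "PC2"]].to_numpy(dtype=float)[keep]
        ids = joined["pair_id"].to_numpy()[keep]
        if family == "lognormal":
            fit = fit_lognormal_regression(y, s, ids=ids)
            cooks = fit.sm_result.get_influence().cooks_distance[0]
        else:
            fit = fit_gamma_glm(y, s, ids=ids)
            cooks = gamma_cooks_distance(fit)
        if not fit.converged:
            unconverged.append(resp)
        d = _fit_to_dict(fit, resp)
        thr = 4.0 / len(y)
        flagged = [
            {"specimen_id": str(i_), "cooks_d": float(c)}
            for i_, c in zip(ids, cooks)
            if c > thr
        ]
        for fl in flagged:
            log.info(
                "analyze: regression outlier response=%s specimen=%s cooks_d=%.4f "
                "(threshold %.4f)", resp, fl["specimen_id"], fl["cooks_d"], thr
            )
        d["outliers"] = {"threshold": thr, "flagged": flagged}
        if flagged and fit.converged:
            keep2 = np.array([c <= thr for c in cooks])
            refit = (
                fit_lognormal_regression(y[keep2], s[keep2], ids=ids[keep2])
                if family == "lognormal"
                else fit_gamma_glm(y[keep2], s[keep2], ids=ids[keep2])
            )
            d["outliers"]["refit_coefficients"] = {
                n: float(c) for n, c in zip(refit.param_names, refit.coefficients)
            }
            log.info("analyze: refit without outliers response=%s coefficients=%s",
                     resp, d["outliers"]["refit_coefficients"])
        if fit.converged:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                diag = simulate_residual_diagnostics(
                    fit, n_sims=config.n_sims_diagnostics, seed=config.seed + 101 + i
                )
            d["diagnostics"] = {
                "dispersion_p": diag.dispersion_p,
                "uniformity_p": diag.uniformity_p,
                "observed_dispersion": diag.observed_dispersion,
                "n_sims": diag.n_sims,
                "seed": diag.seed,
            }
        fits[resp] = fit
        fit_dicts.append(d)

    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "fits").mkdir(exist_ok=True)
    summaries.to_csv(outdir / "summaries.csv", index=False, lineterminator="\n")
    pd.DataFrame(test_rows).to_csv(outdir / "anova_tests.csv", index=False, lineterminator="\n")
    pd.concat(contrast_tables, ignore_index=True).to_csv(
        outdir / "contrasts.csv", index=False, lineterminator="\n"
    )
    pd.DataFrame(
        outlier_rows, columns=["response_name", "specimen_id", "cooks_d", "threshold"]
    ).to_csv(outdir / "outliers.csv", index=False, lineterminator="\n")
    pd.concat(refit_tables, ignore_index=True).to_csv(
        outdir / "outlier_refit_contrasts.csv", index=False, lineterminator="\n"
    )
    loadings.to_csv(outdir / "loadings.csv", lineterminator="\n")
    variance.to_csv(outdir / "pca_variance.csv", index=False, lineterminator="\n")
    scores.to_csv(outdir / "scores.csv", index=False, lineterminator="\n")
    for d in fit_dicts:
        with open(outdir / "fits" / f"{d['response']}.json", "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")
    counts = {
        "summaries": len(summaries),
        "contrasts": sum(len(t) for t in contrast_tables),
        "outliers": len(outlier_rows),
        "fits": len(fit_dicts),
    }
    log.info("analyze: wrote %s", counts)
    _write_manifest(outdir, "analyze", config, counts, warnings_seen)
    if unconverged:
        raise FitError(f"GLM did not converge for response(s): {unconverged}")
    return outdir


def run_report(config: PipelineConfig) -> Path:
    """Render a Markdown report from the machine-readable analysis outputs."""
    data_dir = Path(config.data_dir)
    outdir = Path(config.outdir)
    summaries = pd.read_csv(data_dir / "summaries.csv")
    tests = pd.read_csv(data_dir / "anova_tests.csv")
    variance = pd.read_csv(data_dir / "pca_variance.csv")
    loadings = pd.read_csv(data_dir / "loadings.csv", index_col=0)
    fit_files = sorted((data_dir / "fits").glob("*.json"))
    lines = ["# Endolithic biomass and skeletal morphology: analysis report", ""]
    lines += ["## Species summaries (median ± MAD)", ""]
    for resp, grp in summaries.groupby("response_name"):
        lines.append(f"**{resp}**")
        for _, r in grp.iterrows():
            lines.append(f"- {r['species']}: {r['median']:.3f} ± {r['mad']:.3f} (n={r['n']})")
        lines.append("")
    lines += ["## One-way ANOVA (log scale) and homogeneity of variance", ""]
    for _, r in tests.iterrows():
        lines.append(
            f"- {r['response_name']}: F({r['df_between']:.0f}, {r['df_residual']:.0f}) = "
            f"{r['F']:.3f}, p = {r['p_F']:.3g}; Breusch-Pagan LM = {r['bp_lm']:.3f} "
            f"(df {r['bp_df']:.0f}), p = {r['bp_p']:.3g}"
        )
    lines += ["", "## Principal components", ""]
    for _, r in variance.head(2).iterrows():
        lines.append(
            f"- {r['component']}: eigenvalue {r['eigenvalue']:.3f}, "
            f"{100 * r['variance_fraction']:.1f}% of variance"
        )
    lines.append("")
    lines.append("Loadings (first two components):")
    for var in loadings.index:
        lines.append(
            f"- {var}: PC1 β = {loadings.loc[var, 'PC1']:.3f}, "
            f"PC2 β = {loadings.loc[var, 'PC2']:.3f}"
        )
    lines += ["", "## Regression fits", ""]
    for path in fit_files:
        with open(path) as fh:
            d = json.load(fh)
        c, t, p = d["coefficients"], d["t"], d["p"]
        lines.append(
            f"**{d['response']}** ({d['family']}): "
            f"η = {c['intercept']:.3f} + {c['PC1']:.3f}·PC1 + {c['PC2']:.3f}·PC2; "
            f"PC1 t = {t['PC1']:.3f} (p = {p['PC1']:.3g}), "
            f"PC2 t = {t['PC2']:.3f} (p = {p['PC2']:.3g}); "
            f"φ = {d['phi']:.4f}, α = {d['alpha_shape']:.3f}, "
            f"pseudo-R² = {d['pseudo_r2']:.3f}"
        )
        if "diagnostics" in d:
            dg = d["diagnostics"]
            lines.append(
                f"  - diagnostics: dispersion p = {dg['dispersion_p']:.3f}, "
                f"uniformity p = {dg['uniformity_p']:.3f} ({dg['n_sims']} simulations)"
            )
        if d["outliers"]["flagged"]:
            ids = ", ".join(f["specimen_id"] for f in d["outliers"]["flagged"])
            lines.append(
                f"  - outliers (Cook's D > {d['outliers']['threshold']:.3f}): {ids}; "
                "refit comparison recorded"
            )
        lines.append("")
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.md", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    _write_manifest(outdir, "report", config, {"fits": len(fit_files)}, [])
    return outdir
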