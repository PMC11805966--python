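"""File input/output: moment matrices, YAML model configs, reports."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InputError, NotNestedError, SpecificationError
from .fit import (
    FitResult,
    recover_weights,
    standard_errors,
    standardized_solution,
    weights_se,
)
from .fitstats import chi_square_difference, compute_fit_indices
from .model import CompositeBlock, Latent, ModelSpec
from .moments import SampleMoments


def read_moments(
    path,
    sds_path=None,
    n: int | None = None,
    divisor: str = "unbiased",
) -> SampleMoments:
    """Read a covariance (or correlation) matrix from CSV.

    Accepts a full square matrix (symmetry enforced to 1e-8) or a
    lower-triangular one (empty upper cells are mirrored).  Variable
    names come from the header; an optional leading name column is
    allowed.  If ``sds_path`` is given the matrix is taken to be a
    correlation matrix and converted via ``S_ij = R_ij * sd_i * sd_j``.
    """
    if n is None:
        raise InputError("sample size n is required to interpret a moment matrix")
    df = pd.read_csv(path)
    first = df.columns[0]
    if df[first].dtype == object:
        df = df.set_index(first)
    names = tuple(str(c).strip() for c in df.columns)
    vals = df.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1]:
        raise InputError("moment matrix must be square")
    lower_only = np.isnan(vals[np.triu_indices_from(vals, k=1)]).all() and len(names) > 1
    if lower_only:
        iu = np.triu_indices_from(vals, k=1)
        vals[iu] = vals.T[iu]
    elif np.isnan(vals).any():
        raise InputError("moment matrix contains missing cells")
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise InputError("moment matrix is asymmetric beyond 1e-8")
    if sds_path is not None:
        sds = read_sds(sds_path)
        missing = set(names) - set(sds)
        if missing:
            raise InputError(f"standard deviations missing for {sorted(missing)}")
        s = np.array([sds[v] for v in names])
        vals = vals * np.outer(s, s)
    return SampleMoments(names=names, S=vals, n=int(n), divisor=divisor)


def read_sds(path) -> dict[str, float]:
    """Two-column CSV ``name,sd`` (header optional)."""
    df = pd.read_csv(path, header=None)
    if df.shape[1] != 2:
        raise InputError("standard-deviation file must have two columns: name, sd")
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    return {str(k).strip(): float(v) for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def write_moments(moments: SampleMoments, path) -> None:
    """Write as CSV at 10 significant digits (text round-trip stable)."""
    with open(path, "w") as fh:
        fh.write(",".join(moments.names) + "\n")
        for row in moments.S:
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")


# -- model config -----------------------------------------------------

def model_spec_from_dict(cfg: dict) -> ModelSpec:
    blocks = tuple(
        CompositeBlock(
            name=b["name"],
            components=tuple(b["components"]),
            weight_mode=b.get("weight_mode", "free"),
            shared_component=b.get("shared"),
            references=tuple(b["references"]) if b.get("references") else None,
        )
        for b in cfg.get("blocks", [])
    )
    latents = tuple(
        Latent(l["name"], l["indicator"], float(l.get("reliability", 1.0)))
        for l in cfg.get("latents", [])
    )
    observed = cfg.get("observed")
    if observed is None:
        observed = []
        for b in blocks:
            observed.extend(b.components)
        observed.extend(l.indicator for l in latents)
    spec = ModelSpec(
        observed_names=tuple(observed),
        blocks=blocks,
        latents=latents,
        paths=tuple(tuple(p) for p in cfg.get("paths", [])),
        exo_covariances=tuple(tuple(c) for c in cfg.get("covariances", [])),
        variant=cfg.get("variant", "free"),
    )
    spec.validate()
    return spec


def load_model_config(path) -> ModelSpec:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SpecificationError("model config must be a YAML mapping")
    return model_spec_from_dict(cfg)


# -- reports ----------------------------------------------------------

def fit_report(fit: FitResult) -> dict:
    """JSON-serializable summary of one fitted model."""
    indices = compute_fit_indices(fit)
    report = fit.to_dict()
    report["fit_indices"] = {
        k: (None if isinstance(v, float) and np.isnan(v) else v)
        for k, v in indices.to_dict().items()
    }
    sol = standardized_solution(fit, with_se=True)
    report["standardized_solution"] = sol.to_dict(orient="records")
    report["weights"] = {}
    ses = standard_errors(fit)
    for b in fit.table.blocks:
        if b.scale_method == "one_step":
            # weights are direct model parameters (component -> composite)
            cells = {}
            for c in b.components:
                row = fit.table.find(c, b.name, "path")
                if row is None:
                    continue
                if row.status == "fixed":
                    cells[c] = {"est": float(row.value), "se": 0.0}
                else:
                    cells[c] = {
                        "est": float(fit.estimates[row.label]),
                        "se": float(ses.get(row.label, float("nan"))),
                    }
            report["weights"][b.name] = cells
        else:
            w = recover_weights(fit, b.name)
            se = weights_se(fit, b.name)
            report["weights"][b.name] = {
                c: {"est": float(w[c]), "se": float(se[c])} for c in b.components
            }
    return report


def comparison_report(fits: dict[str, FitResult]) -> dict:
    """Side-by-side comparison of several fitted variants, with
    chi-square difference tests for consecutive nested pairs."""
    report = {"models": {name: fit_report(f) for name, f in fits.items()}}
    comparisons = []
    names = list(fits)
    # consecutive nested pairs only, so a unit < free < relaxed sequence
    # yields the two informative difference tests
    for restricted, full in zip(names, names[1:]):
        try:
            d = chi_square_difference(fits[restricted], fits[full])
        except NotNestedError:
            continue
        comparisons.append(
            {
                "restricted": restricted,
                "full": full,
                "delta_chi_square": d.delta_chi_square,
                "delta_df": d.delta_df,
                "p_value": d.p_value,
            }
        )
    report["comparisons"] = comparisons
    return report


def comparison_text(report: dict) -> str:
    """Aligned plain-text rendering of a comparison report (one column
    per model, rows per statistic)."""
    models = report["models"]
    stats_rows = [
        "chi_square", "df", "p_value", "rmsea", "srmr", "cfi", "tli",
        "aic", "bic", "sabic",
    ]
    frame: dict[str, dict[str, str]] = {}
    for name, rep in models.items():
        col: dict[str, str] = {}
        for b, weights in rep.get("weights", {}).items():
            for comp, cell in weights.items():
                col[f"w_{comp}"] = f"{cell['est']:.3f} ({cell['se']:.3f})"
        for entry in rep["standardized_solution"]:
            arrow = "->" if entry["role"] == "path" else "<->"
            key = f"{entry['source']} {arrow} {entry['target']}"
            se = entry.get("se_std")
            col[key] = f"{entry['std']:.3f}" + (f" ({se:.3f})" if se == se else "")
        for key in stats_rows:
            val = rep["fit_indices"].get(key)
            if val is None:
                col[key] = "NA"
            elif key in ("df",):
                col[key] = str(val)
            else:
                col[key] = f"{val:.3f}"
        frame[name] = col
    df = pd.DataFrame(frame).fillna("NA")
    lines = [df.to_string()]
    for comp in report.get("comparisons", []):
        lines.append(
            f"delta chi-square {comp['restricted']} vs {comp['full']}: "
            f"{comp['delta_chi_square']:.3f} (df={comp['delta_df']}, "
            f"p={comp['p_value']:.4g})"
        )
    return "\n".join(lines)


# -- run configuration ------------------------------------------------

@dataclass
class RunConfig:
    """One analysis run: exactly one input source plus a model config."""

    model_path: str
    moments_path: str | None = None
    sds_path: str | None = None
    n: int | None = None
    data_path: str | None = None
    variants: tuple[str, ...] = ("free",)
    scale_method: str = "effects"
    divisor: str | None = None
    seed: int = 0
    out: str | None = None

    def __post_init__(self):
        if (self.moments_path is None) == (self.data_path is None):
            raise InputError(
                "exactly one input source is required: --moments (with --n) or --data"
            )


def load_input_moments(config: RunConfig) -> SampleMoments:
    if config.moments_path is not None:
        return read_moments(
            config.moments_path,
            sds_path=config.sds_path,
            n=config.n,
            divisor=config.divisor or "unbiased",
        )
    from .moments import moments_from_data

    data = pd.read_csv(config.data_path)
    return moments_from_data(data, divisor=config.divisor or "ml")


def run_analysis(config: RunConfig) -> dict:
    """Fit the requested variants and produce a comparison report."""
    from .estimator import CompositeSEM

    spec = load_model_config(config.model_path)
    moments = load_input_moments(config)
    fits: dict[str, FitResult] = {}
    errors: dict[str, str] = {}
    for variant in config.variants:
        est = CompositeSEM(
            model=spec,
            variant=variant,
            scale_method=config.scale_method,
            seed=config.seed,
        )
        try:
            est.fit(moments)
            fits[variant] = est.result_
        except Exception as exc:  # surfaced with context, partial results kept
            errors[variant] = f"{type(exc).__name__}: {exc}"
    report = comparison_report(fits)
    if errors:
        report["errors"] = errors
    report["converged"] = all(f.converged for f in fits.values()) and not errors
    if config.out:
        out = Path(config.out)
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(json.dumps(report, indent=2, default=float))
        out.with_suffix(".txt").write_text(comparison_text(report) + "\n")
    return report
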