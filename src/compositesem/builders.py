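"""Construction of identified parameter tables.

The Henseler-Ogasawara (H-O) builder turns each composite block of ``k``
components into the composite of interest plus ``k - 1`` excrescent
variables, applying the identification rules of the refined H-O
specification:

1. fix the scale of the composite of interest (effects coding by
   default: its loadings sum to 1; reference-variable and
   variance-standardization methods are available for free weights);
2. each excrescent variable loads on exactly two components -- its
   reference component and the block's shared component -- and no two
   excrescent variables touch the same pair;
3. the reference loading is fixed to 1; the shared loading is free for
   unknown-weight composites and fixed to -1 (sum-to-zero) for
   unit-weight composites;
4. covariances between the composite of interest and its own excrescent
   variables are fixed to 0;
5. an unknown-weight composite must be connected to at least one other
   variable of the model besides its components.

Component error variances are emitted as explicit rows fixed to 0, so
the composites are fully composed of their components.  Single-indicator
latents get their indicator error variance fixed to
``(1 - reliability) * var(indicator)``.
"""
from __future__ import annotations

from typing import Mapping, Sequence

from .exceptions import IdentificationError, SpecificationError
from .model import CompositeBlock, Latent, ModelSpec
from .table import AffineExpr, BlockInfo, LatentInfo, ParamRow, ParameterTable

SCALE_METHODS = ("effects", "reference", "variance_std")


def fixed_error_variance(reliability: float, sd: float) -> float:
    """Error variance implied by an assumed reliability: ``(1 - rel) * sd**2``."""
    if not (0.0 < reliability <= 1.0):
        raise SpecificationError(f"reliability must be in (0, 1], got {reliability}")
    if sd <= 0:
        raise SpecificationError(f"standard deviation must be positive, got {sd}")
    return (1.0 - reliability) * sd * sd


def _indicator_variance(name, indicator_variances, moments):
    if indicator_variances is not None and name in indicator_variances:
        return float(indicator_variances[name])
    if moments is not None:
        return float(moments.variance(name))
    return None


def _latent_rows(spec, rows, indicator_variances, moments):
    for lat in spec.latents:
        rows.append(ParamRow(lat.name, lat.indicator, "loading", "fixed", value=1.0))
        if lat.reliability == 1.0:
            err = 0.0
        else:
            var = _indicator_variance(lat.indicator, indicator_variances, moments)
            if var is None:
                raise SpecificationError(
                    f"indicator variance of {lat.indicator!r} is required to fix its "
                    f"error variance from reliability {lat.reliability}; pass "
                    "`moments` or `indicator_variances`"
                )
            err = fixed_error_variance(lat.reliability, var ** 0.5)
        rows.append(
            ParamRow(lat.indicator, lat.indicator, "variance", "fixed", value=err)
        )
        rows.append(
            ParamRow(lat.name, lat.name, "variance", "free", label=f"v_{lat.name}")
        )


def _structural_rows(spec, rows):
    for src, tgt in spec.paths:
        rows.append(
            ParamRow(src, tgt, "path", "free", start=0.0, label=f"b_{src}_{tgt}")
        )
    endo = spec.endogenous
    for a, b in spec.exo_covariances:
        for name in (a, b):
            if name in endo:
                raise SpecificationError(
                    f"covariance endpoint {name!r} is endogenous; covariances are "
                    "only allowed between exogenous variables"
                )
        rows.append(
            ParamRow(a, b, "covariance", "free", start=0.0, label=f"c_{a}_{b}")
        )


def _plain_observed_rows(spec, rows):
    """Free variances for observed variables with no block/indicator role."""
    comps = set(spec.component_names)
    indicators = {l.indicator for l in spec.latents}
    for name in spec.observed_names:
        if name not in comps and name not in indicators:
            rows.append(
                ParamRow(name, name, "variance", "free", label=f"v_{name}")
            )


def build_ho_specification(
    spec: ModelSpec,
    variant: str | None = None,
    *,
    moments=None,
    indicator_variances: Mapping[str, float] | None = None,
    scale_method: str = "effects",
    enforce_connectivity: bool = True,
) -> ParameterTable:
    """Build the H-O parameter table for ``variant`` in {free, unit, relaxed}.

    ``moments`` or ``indicator_variances`` supply the indicator variances
    needed to fix single-indicator latent error variances from their
    assumed reliabilities.
    """
    variant = variant or spec.variant
    if variant not in ("free", "unit", "relaxed"):
        raise SpecificationError(f"H-O builder got variant {variant!r}")
    if scale_method not in SCALE_METHODS:
        raise SpecificationError(f"unknown scale method {scale_method!r}")
    spec.validate()

    variables = list(spec.observed_names)
    block_infos: list[BlockInfo] = []
    for b in spec.blocks:
        nus = b.excrescent_names()
        variables.append(b.name)
        variables.extend(nus)
        mode = "unit" if variant == "unit" else b.weight_mode
        block_infos.append(
            BlockInfo(b.name, b.components, (b.name,) + nus, mode, scale_method)
        )
    variables.extend(l.name for l in spec.latents)

    rows: list[ParamRow] = []
    connected = {name for pair in spec.paths for name in pair}
    connected |= {name for pair in spec.exo_covariances for name in pair}

    for b, info in zip(spec.blocks, block_infos):
        mode = info.weight_mode
        if mode == "unit" and scale_method != "effects":
            raise SpecificationError(
                "unit-weight composites use effects coding (sum of loadings = 1)"
            )
        if mode == "free" and enforce_connectivity and b.name not in connected:
            raise IdentificationError(
                f"unknown-weight composite {b.name!r} must be connected to at "
                "least one other variable of the model besides its components"
            )
        shared = b.shared
        nus = b.excrescent_names()

        # composite-of-interest loadings
        free_comps = [c for c in b.components if c != shared]
        labels = {c: f"l_{c}_{b.name}" for c in b.components}
        if scale_method == "effects":
            for c in free_comps:
                rows.append(
                    ParamRow(b.name, c, "loading", "free", start=0.0, label=labels[c])
                )
            expr = AffineExpr(1.0, tuple((labels[c], -1.0) for c in free_comps))
            rows.append(ParamRow(b.name, shared, "loading", "constrained", expr=expr))
        elif scale_method == "reference":
            rows.append(ParamRow(b.name, shared, "loading", "fixed", value=1.0))
            for c in free_comps:
                rows.append(
                    ParamRow(b.name, c, "loading", "free", start=0.0, label=labels[c])
                )
        else:  # variance_std
            for c in b.components:
                rows.append(
                    ParamRow(
                        b.name, c, "loading", "free",
                        start=1.0 / b.k, label=labels[c],
                    )
                )

        # excrescent loadings: reference fixed to 1, shared free or -1
        for nu, ref in zip(nus, b.reference_order):
            rows.append(ParamRow(nu, ref, "loading", "fixed", value=1.0))
            if mode == "unit":
                rows.append(ParamRow(nu, shared, "loading", "fixed", value=-1.0))
            else:
                rows.append(
                    ParamRow(
                        nu, shared, "loading", "free",
                        start=0.0, label=f"l_{shared}_{nu}",
                    )
                )

        # variances / covariances of the block's composites
        if scale_method == "variance_std":
            rows.append(ParamRow(b.name, b.name, "variance", "fixed", value=1.0))
        else:
            rows.append(
                ParamRow(b.name, b.name, "variance", "free", label=f"v_{b.name}")
            )
        for nu in nus:
            rows.append(ParamRow(nu, nu, "variance", "free", label=f"v_{nu}"))
            rows.append(ParamRow(b.name, nu, "covariance", "fixed", value=0.0))
        for i, nu_i in enumerate(nus):
            for nu_j in nus[i + 1:]:
                rows.append(
                    ParamRow(
                        nu_i, nu_j, "covariance", "free",
                        start=0.0, label=f"c_{nu_i}_{nu_j}",
                    )
                )

        # component error variances fixed to 0
        for c in b.components:
            rows.append(ParamRow(c, c, "variance", "fixed", value=0.0))

    if variant == "relaxed":
        endo = spec.endogenous
        for i, b in enumerate(spec.blocks):
            for nu in b.excrescent_names():
                for j, other in enumerate(spec.blocks):
                    if other.name == b.name:
                        continue
                    if other.name not in endo:
                        rows.append(
                            ParamRow(
                                nu, other.name, "covariance", "free",
                                start=0.0, label=f"c_{nu}_{other.name}",
                            )
                        )
                    if j > i:
                        for nu2 in other.excrescent_names():
                            rows.append(
                                ParamRow(
                                    nu, nu2, "covariance", "free",
                                    start=0.0, label=f"c_{nu}_{nu2}",
                                )
                            )

    _latent_rows(spec, rows, indicator_variances, moments)
    _structural_rows(spec, rows)
    _plain_observed_rows(spec, rows)

    table = ParameterTable(
        variables=tuple(variables),
        observed=spec.observed_names,
        rows=rows,
        blocks=tuple(block_infos),
        latents=tuple(
            LatentInfo(l.name, l.indicator, l.reliability) for l in spec.latents
        ),
    )
    table.validate()
    return table


def build_one_step_specification(
    spec: ModelSpec,
    *,
    moments=None,
    indicator_variances: Mapping[str, float] | None = None,
    fixed_components: Mapping[str, str | None] | None = None,
) -> ParameterTable:
    """One-step baseline: each composite is an endogenous variable
    regressed on its exogenous observed components, with its disturbance
    variance fixed to 0 and one component coefficient fixed to 1 (the
    last component by default).  All component variances and covariances,
    within and across blocks, are free.
    """
    spec.validate()
    fixed_components = dict(fixed_components or {})
    block_names = {b.name for b in spec.blocks}
    for a, b in spec.exo_covariances:
        if a in block_names and b in block_names:
            raise SpecificationError(
                f"it is not possible to specify a covariance between the one-step "
                f"composites {a!r} and {b!r}"
            )

    variables = list(spec.observed_names) + [b.name for b in spec.blocks]
    variables += [l.name for l in spec.latents]
    rows: list[ParamRow] = []
    outgoing = {src for src, _ in spec.paths}

    def weight_starts(block, fixed):
        """Leading canonical-correlation direction between the block's
        components and the remaining observed variables, scaled so the
        fixed component gets weight 1.  Free composite weights estimate
        exactly this kind of direction, so it is a well-placed start
        (plain unit starts can sit in a wrong-sign basin)."""
        if moments is None:
            return {c: 1.0 for c in block.components}
        import numpy as np

        names = list(moments.names)
        others = [v for v in spec.observed_names if v not in block.components]
        ix = [names.index(c) for c in block.components]
        iy = [names.index(o) for o in others]
        S = moments.S
        Sxx, Sxy, Syy = S[np.ix_(ix, ix)], S[np.ix_(ix, iy)], S[np.ix_(iy, iy)]
        try:
            M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
            vals, vecs = np.linalg.eig(M)
            w = np.real(vecs[:, np.argmax(np.real(vals))])
            pivot = w[block.components.index(fixed)]
            if abs(pivot) < 1e-10:
                raise np.linalg.LinAlgError
            w = w / pivot
        except np.linalg.LinAlgError:
            return {c: 1.0 for c in block.components}
        return dict(zip(block.components, w))

    all_components: list[str] = list(spec.component_names)
    for b in spec.blocks:
        if b.weight_mode == "unit":
            for c in b.components:
                rows.append(ParamRow(c, b.name, "path", "fixed", value=1.0))
        else:
            fixed = fixed_components.get(b.name, b.components[-1])
            if fixed is None:
                raise IdentificationError(
                    f"composite {b.name!r} has no fixed weight: its scale is "
                    "indeterminate"
                )
            if fixed not in b.components:
                raise SpecificationError(
                    f"{fixed!r} is not a component of {b.name!r}"
                )
            if b.name not in outgoing:
                raise IdentificationError(
                    f"unknown-weight composite {b.name!r} must affect at least one "
                    "other variable of the model"
                )
            starts = weight_starts(b, fixed)
            for c in b.components:
                if c == fixed:
                    rows.append(ParamRow(c, b.name, "path", "fixed", value=1.0))
                else:
                    rows.append(
                        ParamRow(
                            c, b.name, "path", "free",
                            start=float(starts[c]), label=f"w_{c}_{b.name}",
                        )
                    )
        rows.append(ParamRow(b.name, b.name, "variance", "fixed", value=0.0))

    # components: free variances and covariances, within and across blocks
    for i, a in enumerate(all_components):
        rows.append(ParamRow(a, a, "variance", "free", label=f"v_{a}"))
        for b_ in all_components[i + 1:]:
            rows.append(
                ParamRow(a, b_, "covariance", "free", start=0.0, label=f"c_{a}_{b_}")
            )

    _latent_rows(spec, rows, indicator_variances, moments)
    _structural_rows(spec, rows)
    _plain_observed_rows(spec, rows)

    table = ParameterTable(
        variables=tuple(variables),
        observed=spec.observed_names,
        rows=rows,
        blocks=tuple(
            BlockInfo(b.name, b.components, (b.name,), b.weight_mode, "one_step")
            for b in spec.blocks
        ),
        latents=tuple(
            LatentInfo(l.name, l.indicator, l.reliability) for l in spec.latents
        ),
    )
    table.validate()
    return table


def build_structural_specification(
    spec: ModelSpec,
    *,
    moments=None,
    indicator_variances: Mapping[str, float] | None = None,
) -> ParameterTable:
    """Plain structural model without composite blocks (two-step stage two)."""
    if spec.blocks:
        raise SpecificationError("structural builder expects a spec without blocks")
    return build_ho_specification(
        spec, "free", moments=moments, indicator_variances=indicator_variances
    )
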