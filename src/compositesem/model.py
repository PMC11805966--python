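"""Declarative model description.

A :class:`ModelSpec` describes a structural model over observed variables,
composite blocks (emergent variables formed from observed components),
and single-indicator latent variables with an assumed reliability.  It is
purely declarative; parameter tables are produced by the builders in
:mod:`compositesem.builders`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx

from .exceptions import SpecificationError

VARIANTS = ("free", "unit", "relaxed", "one_step", "two_step")


@dataclass(frozen=True)
class CompositeBlock:
    """One composite of interest plus the implied excrescent variables.

    Parameters
    ----------
    name:
        Name of the composite of interest (e.g. ``"Soil"``).
    components:
        Ordered observed components, ``k >= 2``.
    weight_mode:
        ``"free"`` (unknown weights, estimated) or ``"unit"`` (the
        composite is the plain sum of its components).
    shared_component:
        The component whose loadings on the excrescent variables are
        freed in free-weight mode.  Every excrescent variable touches
        exactly this component and one reference component.  Defaults to
        the first component.
    references:
        Ordered assignment of one distinct reference component per
        excrescent variable; defaults to the non-shared components in
        declared order.  No component may serve as reference twice.
    """

    name: str
    components: tuple[str, ...]
    weight_mode: str = "free"
    shared_component: str | None = None
    references: tuple[str, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        if self.references is not None:
            object.__setattr__(self, "references", tuple(self.references))
        if len(self.components) < 2:
            raise SpecificationError(f"block {self.name!r} needs at least 2 components")
        if self.weight_mode not in ("free", "unit"):
            raise SpecificationError(f"unknown weight_mode {self.weight_mode!r}")

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def shared(self) -> str:
        return self.shared_component or self.components[0]

    @property
    def reference_order(self) -> tuple[str, ...]:
        refs = self.references
        if refs is None:
            refs = tuple(c for c in self.components if c != self.shared)
        return refs

    def validate(self) -> None:
        if len(set(self.components)) != len(self.components):
            raise SpecificationError(f"block {self.name!r} repeats a component")
        if self.shared not in self.components:
            raise SpecificationError(
                f"shared component {self.shared!r} is not a component of {self.name!r}"
            )
        refs = self.reference_order
        if len(refs) != self.k - 1:
            raise SpecificationError(
                f"block {self.name!r} needs {self.k - 1} references, got {len(refs)}"
            )
        if len(set(refs)) != len(refs):
            raise SpecificationError(
                f"block {self.name!r}: no component may serve as reference twice"
            )
        if self.shared in refs:
            raise SpecificationError(
                f"block {self.name!r}: shared component cannot also be a reference"
            )
        if not set(refs) <= set(self.components):
            raise SpecificationError(
                f"block {self.name!r}: references must be components"
            )

    def excrescent_names(self) -> tuple[str, ...]:
        return tuple(f"{self.name}_nu{i + 1}" for i in range(self.k - 1))


@dataclass(frozen=True)
class Latent:
    """Single-indicator latent variable with an assumed reliability."""

    name: str
    indicator: str
    reliability: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.reliability <= 1.0):
            raise SpecificationError(
                f"reliability of {self.name!r} must be in (0, 1], got {self.reliability}"
            )


@dataclass(frozen=True)
class ModelSpec:
    observed_names: tuple[str, ...]
    blocks: tuple[CompositeBlock, ...] = ()
    latents: tuple[Latent, ...] = ()
    paths: tuple[tuple[str, str], ...] = ()
    exo_covariances: tuple[tuple[str, str], ...] = ()
    variant: str = "free"

    def __post_init__(self):
        object.__setattr__(self, "observed_names", tuple(self.observed_names))
        object.__setattr__(self, "blocks", tuple(self.blocks))
        object.__setattr__(self, "latents", tuple(self.latents))
        object.__setattr__(self, "paths", tuple(tuple(p) for p in self.paths))
        object.__setattr__(
            self, "exo_covariances", tuple(tuple(c) for c in self.exo_covariances)
        )

    # -- derived -----------------------------------------------------
    @property
    def construct_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.blocks) + tuple(l.name for l in self.latents)

    @property
    def component_names(self) -> tuple[str, ...]:
        out: list[str] = []
        for b in self.blocks:
            out.extend(b.components)
        return tuple(out)

    @property
    def endogenous(self) -> frozenset[str]:
        return frozenset(t for _, t in self.paths)

    def block(self, name: str) -> CompositeBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise SpecificationError(f"unknown variant {self.variant!r}")
        obs = self.observed_names
        if len(set(obs)) != len(obs):
            raise SpecificationError("observed variable names must be unique")
        for b in self.blocks:
            b.validate()
            missing = set(b.components) - set(obs)
            if missing:
                raise SpecificationError(
                    f"block {b.name!r} uses undeclared components {sorted(missing)}"
                )
        comps = self.component_names
        if len(set(comps)) != len(comps):
            raise SpecificationError("component names must be disjoint across blocks")
        indicators = [l.indicator for l in self.latents]
        if len(set(indicators)) != len(indicators):
            raise SpecificationError("each indicator may measure only one latent")
        if set(indicators) & set(comps):
            raise SpecificationError(
                "latent indicators must be disjoint from block components"
            )
        for l in self.latents:
            if l.indicator not in obs:
                raise SpecificationError(
                    f"indicator {l.indicator!r} of {l.name!r} is not observed"
                )
        names = list(obs) + [b.name for b in self.blocks]
        for b in self.blocks:
            names.extend(b.excrescent_names())
        names += [l.name for l in self.latents]
        if len(set(names)) != len(names):
            raise SpecificationError("variable names collide across roles")
        valid_endpoints = set(obs) | set(self.construct_names)
        for src, tgt in self.paths:
            for name in (src, tgt):
                if name not in valid_endpoints:
                    raise SpecificationError(f"path endpoint {name!r} is not declared")
            if src == tgt:
                raise SpecificationError(f"self-loop path on {src!r}")
        for a, b_ in self.exo_covariances:
            for name in (a, b_):
                if name not in valid_endpoints:
                    raise SpecificationError(
                        f"covariance endpoint {name!r} is not declared"
                    )
        graph = nx.DiGraph()
        graph.add_nodes_from(valid_endpoints)
        graph.add_edges_from(self.paths)
        if not nx.is_directed_acyclic_graph(graph):
            raise SpecificationError("the structural graph must be acyclic")


def one_step_spec(spec: ModelSpec) -> ModelSpec:
    """Drop composite-composite covariances (unspecifiable in one-step form)."""
    block_names = {b.name for b in spec.blocks}
    covs = tuple(
        (a, b)
        for a, b in spec.exo_covariances
        if not (a in block_names and b in block_names)
    )
    return replace(spec, exo_covariances=covs, variant="one_step")


def two_step_spec(spec: ModelSpec) -> ModelSpec:
    """Stage-two model of the two-step approach: composite scores become
    plain observed variables, blocks disappear."""
    comps = set(spec.component_names)
    observed = tuple(b.name for b in spec.blocks) + tuple(
        v for v in spec.observed_names if v not in comps
    )
    return ModelSpec(
        observed_names=observed,
        blocks=(),
        latents=spec.latents,
        paths=spec.paths,
        exo_covariances=spec.exo_covariances,
        variant="two_step",
    )
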