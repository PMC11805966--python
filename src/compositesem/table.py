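"""Constrained parameter tables.

A :class:`ParameterTable` is the bridge between a declarative model
description and the covariance engine: a list of rows, one per model
parameter, each either *free* (estimated, carries a label), *fixed* at a
numeric value, or *constrained* to an affine expression over the free
labels (e.g. an effects-coding loading ``1 - l_a - l_b``).  Given values
for all free labels the table determines one full parameter assignment,
from which the model-implied covariance matrix follows.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .exceptions import OverparameterizedModelError, SpecificationError

ROLES = ("loading", "path", "variance", "covariance")
STATUSES = ("free", "fixed", "constrained")

_TOKEN = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_.]*)"
    r"|(?P<op>[*+-]))"
)


@dataclass(frozen=True)
class AffineExpr:
    """Affine expression ``const + sum(coef * label)`` over free labels."""

    const: float = 0.0
    terms: tuple[tuple[str, float], ...] = ()

    def labels(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.terms)

    def evaluate(self, values: Mapping[str, float]) -> float:
        try:
            return self.const + sum(c * values[name] for name, c in self.terms)
        except KeyError as exc:  # pragma: no cover - guarded by validate()
            raise SpecificationError(f"expression references unknown label {exc}")

    def __str__(self) -> str:
        parts: list[str] = []
        if self.const or not self.terms:
            parts.append(f"{self.const:.17g}")
        for name, coef in self.terms:
            sign = "-" if coef < 0 else "+"
            mag = abs(coef)
            term = name if mag == 1 else f"{mag:.17g}*{name}"
            if not parts:
                parts.append(term if sign == "+" else f"-{term}")
            else:
                parts.append(f"{sign} {term}")
        return " ".join(parts)

    @classmethod
    def parse(cls, text: str) -> "AffineExpr":
        """Parse strings like ``"1 - l_a - 0.5*l_b"``."""
        tokens: list[str] = []
        pos = 0
        text = text.strip()
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if m is None:
                raise SpecificationError(f"cannot parse expression: {text!r}")
            tokens.append(m.group(m.lastgroup))
            pos = m.end()
        const = 0.0
        terms: list[tuple[str, float]] = []
        sign = 1.0
        i = 0
        while i < len(tokens):
            tok = tokens[i]
            if tok == "+":
                i += 1
                continue
            if tok == "-":
                sign = -sign
                i += 1
                continue
            coef = sign
            name = None
            if re.match(r"^[\d.]", tok):
                coef = sign * float(tok)
                if i + 2 < len(tokens) and tokens[i + 1] == "*":
                    name = tokens[i + 2]
                    i += 3
                else:
                    i += 1
            else:
                name = tok
                i += 1
            if name is None:
                const += coef
            else:
                terms.append((name, coef))
            sign = 1.0
        return cls(const=const, terms=tuple(terms))


@dataclass(frozen=True)
class ParamRow:
    """One parameter of the model.

    ``loading`` and ``path`` rows place a coefficient ``target <- source``
    in the asymmetric matrix; ``variance``/``covariance`` rows fill the
    symmetric matrix of exogenous/residual (co)variances.
    """

    source: str
    target: str
    role: str
    status: str
    value: float | None = None
    expr: AffineExpr | None = None
    start: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SpecificationError(f"unknown role {self.role!r}")
        if self.status not in STATUSES:
            raise SpecificationError(f"unknown status {self.status!r}")
        if self.role == "variance" and self.source != self.target:
            raise SpecificationError("variance rows must have source == target")
        if self.status == "free" and not self.label:
            raise SpecificationError("free rows require a label")
        if self.status == "fixed" and self.value is None:
            raise SpecificationError("fixed rows require a value")
        if self.status == "constrained" and self.expr is None:
            raise SpecificationError("constrained rows require an expression")


@dataclass(frozen=True)
class BlockInfo:
    """Layout of one composite block inside a table.

    ``composites`` lists the composite of interest first, then the
    excrescent variables, matching the column order of the block's
    loading matrix.
    """

    name: str
    components: tuple[str, ...]
    composites: tuple[str, ...]
    weight_mode: str = "free"
    scale_method: str = "effects"


@dataclass(frozen=True)
class LatentInfo:
    name: str
    indicator: str
    reliability: float


@dataclass
class ParameterTable:
    """Rows plus the variable bookkeeping the covariance engine needs."""

    variables: tuple[str, ...]
    observed: tuple[str, ...]
    rows: list[ParamRow] = field(default_factory=list)
    blocks: tuple[BlockInfo, ...] = ()
    latents: tuple[LatentInfo, ...] = ()

    # -- structure ---------------------------------------------------
    @property
    def free_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for row in self.rows:
            if row.status == "free":
                seen[row.label] = None
        return tuple(seen)

    @property
    def q(self) -> int:
        return len(self.free_labels)

    def dof(self, p: int | None = None) -> int:
        return count_degrees_of_freedom(self, p)

    def find(self, source: str, target: str, role: str) -> ParamRow | None:
        for row in self.rows:
            if row.role != role:
                continue
            if {row.source, row.target} == {source, target}:
                return row
        return None

    def validate(self) -> None:
        declared = set(self.variables)
        labels = [r.label for r in self.rows if r.status == "free"]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise SpecificationError(f"duplicate free labels: {dupes}")
        free = set(labels)
        for row in self.rows:
            for name in (row.source, row.target):
                if name not in declared:
                    raise SpecificationError(f"row references unknown variable {name!r}")
            if row.status == "constrained":
                unknown = set(row.expr.labels()) - free
                if unknown:
                    raise SpecificationError(
                        f"constraint references unknown labels {sorted(unknown)}"
                    )

    # -- serialization ----------------------------------------------
    def to_csv(self, path) -> None:
        meta = {
            "variables": list(self.variables),
            "observed": list(self.observed),
            "blocks": [
                {
                    "name": b.name,
                    "components": list(b.components),
                    "composites": list(b.composites),
                    "weight_mode": b.weight_mode,
                    "scale_method": b.scale_method,
                }
                for b in self.blocks
            ],
            "latents": [
                {"name": l.name, "indicator": l.indicator, "reliability": l.reliability}
                for l in self.latents
            ],
        }
        with open(path, "w") as fh:
            fh.write("#meta " + json.dumps(meta) + "\n")
            fh.write("source,target,role,status,value_or_expression,label\n")
            for row in self.rows:
                if row.status == "free":
                    val = "" if row.start is None else f"{row.start:.10g}"
                elif row.status == "fixed":
                    val = f"{row.value:.10g}"
                else:
                    val = str(row.expr)
                fh.write(
                    f"{row.source},{row.target},{row.role},{row.status},"
                    f"\"{val}\",{row.label or ''}\n"
                )

    @classmethod
    def from_csv(cls, path) -> "ParameterTable":
        import csv

        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#meta "):
                raise SpecificationError("table CSV is missing its #meta header line")
            meta = json.loads(first[len("#meta "):])
            reader = csv.DictReader(fh)
            rows: list[ParamRow] = []
            for rec in reader:
                status = rec["status"]
                val = rec["value_or_expression"]
                kwargs: dict = {}
                if status == "free":
                    kwargs["label"] = rec["label"]
                    if val:
                        kwargs["start"] = float(val)
                elif status == "fixed":
                    kwargs["value"] = float(val)
                else:
                    kwargs["expr"] = AffineExpr.parse(val)
                rows.append(
                    ParamRow(rec["source"], rec["target"], rec["role"], status, **kwargs)
                )
        table = cls(
            variables=tuple(meta["variables"]),
            observed=tuple(meta["observed"]),
            rows=rows,
            blocks=tuple(
                BlockInfo(
                    b["name"],
                    tuple(b["components"]),
                    tuple(b["composites"]),
                    b["weight_mode"],
                    b["scale_method"],
                )
                for b in meta["blocks"]
            ),
            latents=tuple(
                LatentInfo(l["name"], l["indicator"], l["reliability"])
                for l in meta["latents"]
            ),
        )
        table.validate()
        return table


def count_degrees_of_freedom(table: ParameterTable, p: int | None = None) -> int:
    """``p(p+1)/2 - q`` (no mean structure is modeled)."""
    if p is None:
        p = len(table.observed)
    df = p * (p + 1) // 2 - table.q
    if df < 0:
        raise OverparameterizedModelError(
            f"{table.q} free parameters exceed {p * (p + 1) // 2} non-redundant moments"
        )
    return df
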