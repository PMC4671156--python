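"""Declarative criteria configuration: parsing, validation, presets.

A run is described by a YAML/JSON-style document::

    feature_id: Probeset          # ID column of the input table
    criteria:
      - name: p_value
        column: p_value
        function: low             # high | low | central | ends | categorical | sigmoid
        cut1: 0.0001
        cut2: 0.1
        weight: 1.0
      - name: fold_change
        column: logFC
        function: ends
        cut1: "q:0.05"            # quantile placeholder, resolved from the data
        cut2: "q:0.25"
        cut3: "q:0.75"
        cut4: "q:0.95"
        weight: 1.0
    output:
      threshold: 0.7              # or: k: 50
      comparison_rank:
        column: p_value
        ascending: true
        prefilters:
          - {column: AveExpr, op: ">=", value: 6.0}

Validation resolves every criterion into a typed spec and reports *all*
problems at once (each tagged with the criterion name and field) rather than
stopping at the first.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from . import functions as fn
from .errors import ConfigError, DesirankError
from .pipeline import Criterion, Prefilter, QuantileCut

__all__ = [
    "ComparisonSpec",
    "OutputSpec",
    "RunConfig",
    "validate_config",
    "load_config",
    "load_preset",
    "list_presets",
    "criterion_to_dict",
    "write_provenance",
]

_FUNCTIONS = ("high", "low", "central", "ends", "categorical", "sigmoid")


@dataclass(frozen=True)
class ComparisonSpec:
    """Column-sort baseline ranking (e.g. rank by p-value) with optional
    keep-prefilters applied first."""

    column: str
    ascending: bool = True
    prefilters: tuple = ()


@dataclass(frozen=True)
class OutputSpec:
    threshold: Optional[float] = None
    k: Optional[int] = None
    comparison: Optional[ComparisonSpec] = None


@dataclass(frozen=True)
class RunConfig:
    """A fully validated run: typed criteria plus output options."""

    criteria: tuple
    feature_id: Optional[str] = None
    output: OutputSpec = field(default_factory=OutputSpec)

    @property
    def weights(self) -> list[float]:
        return [c.weight for c in self.criteria]


def _parse_cut(value, where: str, problems: list):
    if isinstance(value, str):
        if value.startswith("q:"):
            try:
                return QuantileCut(float(value[2:]))
            except (ValueError, ConfigError):
                problems.append(f"{where}: bad quantile placeholder {value!r}")
                return QuantileCut(0.5)
        problems.append(
            f"{where}: expected a number or 'q:<fraction>', got {value!r}"
        )
        return 0.0
    if value is None:
        problems.append(f"{where}: cut point is missing")
        return 0.0
    try:
        return float(value)
    except (TypeError, ValueError):
        problems.append(f"{where}: expected a number, got {value!r}")
        return 0.0


def _build_spec(entry: dict, name: str, problems: list):
    function = entry.get("function")
    if function not in _FUNCTIONS:
        problems.append(
            f"criterion {name!r}: function must be one of {_FUNCTIONS}, "
            f"got {function!r}"
        )
        return None
    common = {}
    for key in ("des_min", "des_max", "scale"):
        if key in entry:
            common[key] = entry[key]
    try:
        if function in ("high", "low"):
            return fn.MonotoneSpec(
                cut1=_parse_cut(entry.get("cut1"), f"criterion {name!r}: cut1", problems),
                cut2=_parse_cut(entry.get("cut2"), f"criterion {name!r}: cut2", problems),
                direction=function,
                **common,
            )
        if function in ("central", "ends"):
            return fn.PlateauSpec(
                cut1=_parse_cut(entry.get("cut1"), f"criterion {name!r}: cut1", problems),
                cut2=_parse_cut(entry.get("cut2"), f"criterion {name!r}: cut2", problems),
                cut3=_parse_cut(entry.get("cut3"), f"criterion {name!r}: cut3", problems),
                cut4=_parse_cut(entry.get("cut4"), f"criterion {name!r}: cut4", problems),
                direction=function,
                **common,
            )
        if function == "categorical":
            mapping = entry.get("mapping")
            if not isinstance(mapping, dict) or not mapping:
                problems.append(
                    f"criterion {name!r}: categorical function needs a "
                    f"non-empty 'mapping'"
                )
                return None
            common.pop("scale", None)
            common.pop("des_min", None)
            common.pop("des_max", None)
            return fn.CategoricalSpec(
                mapping=mapping, default=entry.get("default", "error")
            )
        common.pop("scale", None)
        return fn.SigmoidSpec(
            midpoint=_parse_cut(
                entry.get("midpoint"), f"criterion {name!r}: midpoint", problems
            ),
            steepness=float(entry.get("steepness", 0.0)),
            **common,
        )
    except DesirankError as exc:
        problems.append(f"criterion {name!r}: {exc}")
        return None


def _build_output(doc: dict, problems: list) -> OutputSpec:
    out = doc.get("output") or {}
    if not isinstance(out, dict):
        problems.append("output section must be a mapping")
        return OutputSpec()
    threshold = out.get("threshold")
    k = out.get("k")
    if threshold is not None and k is not None:
        problems.append("output: give only one of threshold or k")
    if threshold is not None and not (0.0 <= float(threshold) <= 1.0):
        problems.append(f"output: threshold must be in [0, 1], got {threshold}")
    if k is not None and int(k) < 1:
        problems.append(f"output: k must be a positive integer, got {k}")
    comparison = None
    comp = out.get("comparison_rank")
    if comp is not None:
        if not isinstance(comp, dict) or "column" not in comp:
            problems.append("output.comparison_rank needs a 'column'")
        else:
            prefilters = []
            for i, p in enumerate(comp.get("prefilters") or []):
                try:
                    prefilters.append(
                        Prefilter(p["column"], p["op"], float(p["value"]))
                    )
                except (KeyError, TypeError, ValueError, ConfigError) as exc:
                    problems.append(
                        f"output.comparison_rank.prefilters[{i}]: {exc}"
                    )
            comparison = ComparisonSpec(
                column=comp["column"],
                ascending=bool(comp.get("ascending", True)),
                prefilters=tuple(prefilters),
            )
    return OutputSpec(
        threshold=None if threshold is None else float(threshold),
        k=None if k is None else int(k),
        comparison=comparison,
    )


def validate_config(document: dict) -> RunConfig:
    """Resolve a raw config document into typed criteria.

    Every schema violation is collected and reported together in a single
    :class:`ConfigError`, each message naming the criterion and field.
    """
    problems: list[str] = []
    if not isinstance(document, dict):
        raise ConfigError(["config document must be a mapping"])
    entries = document.get("criteria")
    if not entries:
        problems.append("config must list at least one criterion")
        entries = []
    criteria = []
    seen = set()
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict):
            problems.append(f"criteria[{i}]: must be a mapping")
            continue
        name = entry.get("name") or entry.get("column") or f"criterion_{i}"
        if name in seen:
            problems.append(f"criterion {name!r}: duplicate name")
        seen.add(name)
        column = entry.get("column")
        if not column:
            problems.append(f"criterion {name!r}: missing 'column'")
        weight = entry.get("weight", 1.0)
        try:
            weight = float(weight)
        except (TypeError, ValueError):
            problems.append(f"criterion {name!r}: weight must be a number")
            weight = 1.0
        if weight < 0:
            problems.append(f"criterion {name!r}: weight must be >= 0")
        spec = _build_spec(entry, name, problems)
        if spec is not None and column and weight >= 0:
            try:
                criteria.append(Criterion(name, column, spec, weight))
            except DesirankError as exc:
                problems.append(str(exc))
    output = _build_output(document, problems)
    if problems:
        raise ConfigError(problems)
    return RunConfig(
        criteria=tuple(criteria),
        feature_id=document.get("feature_id"),
        output=output,
    )


def load_config(path) -> RunConfig:
    """Read and validate a YAML criteria configuration file."""
    with open(path) as fh:
        document = yaml.safe_load(fh)
    return validate_config(document)


def list_presets() -> list[str]:
    root = resources.files("desirank.presets")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str, validate: bool = True):
    """Load a shipped criteria preset by name.

    With ``validate=True`` (default) returns a :class:`RunConfig`; otherwise
    the raw document, useful as a starting point for editing.
    """
    ref = resources.files("desirank.presets") / f"{name}.yaml"
    if not ref.is_file():
        raise ConfigError(
            [f"unknown preset {name!r}; available: {list_presets()}"]
        )
    document = yaml.safe_load(ref.read_text())
    return validate_config(document) if validate else document


def criterion_to_dict(criterion: Criterion) -> dict:
    """Serialisable form of a (possibly resolved) criterion, for run logs."""
    spec = criterion.spec
    entry: dict = {
        "name": criterion.name,
        "column": criterion.column,
        "weight": criterion.weight,
    }
    if isinstance(spec, fn.MonotoneSpec):
        entry["function"] = spec.direction
    elif isinstance(spec, fn.PlateauSpec):
        entry["function"] = spec.direction
    elif isinstance(spec, fn.CategoricalSpec):
        entry["function"] = "categorical"
        entry["mapping"] = {str(k): v for k, v in spec.mapping.items()}
        entry["default"] = spec.default
        return entry
    else:
        entry["function"] = "sigmoid"
    for f_name in ("cut1", "cut2", "cut3", "cut4", "midpoint", "steepness",
                   "des_min", "des_max", "scale"):
        if hasattr(spec, f_name):
            value = getattr(spec, f_name)
            if isinstance(value, QuantileCut):
                value = f"q:{value.q}"
            entry[f_name] = value
    return entry


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    out_path,
    criteria,
    inputs=(),
    seed: Optional[int] = None,
    extra: Optional[dict] = None,
) -> Path:
    """Write a JSON provenance record next to an output file.

    Records the fully resolved criteria (functions, cut points, weights --
    the decision criteria that make the run reproducible), the seed, and a
    digest of every input file.
    """
    from . import __version__

    record = {
        "desirank_version": __version__,
        "created_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(
            timespec="seconds"
        ),
        "seed": seed,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "criteria": [criterion_to_dict(c) for c in criteria],
    }
    if extra:
        record.update(extra)
    path = Path(f"{out_path}.provenance.json")
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return path
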