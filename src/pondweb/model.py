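"""Data model, validation and file I/O for mass-balance food-web models.

A pond (or any closed aquaculture system) is described by a list of
functional groups — consumers, primary producers and detritus pools — a
diet-composition matrix, and per-group rate parameters expressed over a
fixed culture period (here 300 days).  Import-fed pools such as
formulated feed and atmospheric/terrestrial precipitation are modelled
as detritus-category groups carrying a nonzero import, so they enter
the web as ordinary prey of level 1.

Parameters follow the Ecopath convention:

``B``      biomass, g m^-2 (wet weight)
``P/B``    production/biomass rate, per period
``Q/B``    consumption/biomass rate, per period
``EE``     ecotrophic efficiency — the fraction of production used
           within the system (eaten, caught or otherwise removed)
``GS``     unassimilated fraction of consumption (egestion)

Any one of ``{B, P/B, Q/B, EE}`` may be left unknown for a living group
and recovered by :func:`pondweb.balance.solve_missing`.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONSUMER = "consumer"
PRODUCER = "producer"
DETRITUS = "detritus"
CATEGORIES = (CONSUMER, PRODUCER, DETRITUS)

#: dispositions for detritus surplus left unrouted by the fate vector
SURPLUS_EXPORT = "export"
SURPLUS_ACCUMULATION = "accumulation"

_GROUP_COLUMNS = [
    "name", "category", "biomass", "pb", "qb", "ee", "gs",
    "catch", "import", "ba", "migration", "surplus_disposition",
]

DIET_TOL = 1e-6


class ModelError(ValueError):
    """Raised for unusable model definitions (parse or invariant failures)."""


@dataclass
class Group:
    """One functional group of the web.

    ``None`` marks a parameter as unknown (solvable).  ``detritus_fate``
    maps detritus-group names to the fraction of this group's flow to
    detritus (or, for a detritus group, of its surplus) routed there;
    any shortfall relative to 1 leaves the system.
    """

    name: str
    category: str
    biomass: float | None = None
    pb: float | None = None
    qb: float | None = None
    ee: float | None = None
    gs: float = 0.0
    catch: float = 0.0
    imports: float = 0.0
    ba: float = 0.0
    migration: float = 0.0
    detritus_fate: dict[str, float] = field(default_factory=dict)
    surplus_disposition: str = SURPLUS_EXPORT

    @property
    def is_living(self) -> bool:
        return self.category in (CONSUMER, PRODUCER)

    def unknowns(self) -> list[str]:
        """Names of the unresolved parameters among {biomass, pb, qb, ee}."""
        return [p for p in ("biomass", "pb", "qb", "ee")
                if getattr(self, p) is None]


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: ``errors`` reject a model, ``warnings``
    flag suspicious but usable input."""

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    def error(self, group: str, rule: str, message: str) -> None:
        self.errors.append((group, rule, message))

    def warn(self, group: str, rule: str, message: str) -> None:
        self.warnings.append((group, rule, message))

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_failed(self) -> None:
        if self.errors:
            group, rule, message = self.errors[0]
            raise ModelError(f"[{group}] {rule}: {message}")


class EcopathModel:
    """A food-web model: ordered groups, a diet matrix and a period.

    ``diet[j, i]`` is the fraction of prey ``i`` in the diet of predator
    ``j`` (predator-major, matching the column orientation of printed
    prey-by-predator diet tables once transposed).  Group order is
    preserved exactly as given.
    """

    def __init__(self, groups: list[Group], diet: np.ndarray,
                 period_days: int = 300, label: str = ""):
        self.groups = list(groups)
        self.diet = np.asarray(diet, dtype=float)
        self.period_days = int(period_days)
        self.label = label
        if self.diet.shape != (len(self.groups), len(self.groups)):
            raise ModelError(
                f"diet matrix shape {self.diet.shape} does not match "
                f"{len(self.groups)} groups")

    # -- structural helpers -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.groups)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def group(self, name: str) -> Group:
        return self.groups[self.index(name)]

    def mask(self, category: str) -> np.ndarray:
        return np.array([g.category == category for g in self.groups])

    @property
    def living(self) -> np.ndarray:
        return self.mask(CONSUMER) | self.mask(PRODUCER)

    @property
    def detritus_names(self) -> list[str]:
        return [g.name for g in self.groups if g.category == DETRITUS]

    def param(self, attr: str, fill: float = np.nan) -> np.ndarray:
        """Vector of a per-group parameter with ``None`` mapped to ``fill``."""
        return np.array([fill if getattr(g, attr) is None else getattr(g, attr)
                         for g in self.groups], dtype=float)

    def fate_matrix(self) -> np.ndarray:
        """``(n, n)`` routing matrix: fraction of group *i*'s detritus flow
        (or surplus) directed to detritus group *d*.  Columns of
        non-detritus groups are zero."""
        out = np.zeros((self.n, self.n))
        idx = {name: k for k, name in enumerate(self.names)}
        for i, g in enumerate(self.groups):
            for name, frac in g.detritus_fate.items():
                out[i, idx[name]] = frac
        return out

    def copy(self) -> "EcopathModel":
        groups = [replace(g, detritus_fate=dict(g.detritus_fate))
                  for g in self.groups]
        return EcopathModel(groups, self.diet.copy(), self.period_days,
                            self.label)

    def diet_frame(self) -> pd.DataFrame:
        """Diet matrix in the printed prey-by-predator orientation."""
        return pd.DataFrame(self.diet.T, index=self.names, columns=self.names)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"EcopathModel({self.label or 'unlabelled'}: {self.n} groups, "
                f"{self.period_days}-day period)")


# ---------------------------------------------------------------------------
# validation

def validate(model: EcopathModel) -> ValidationReport:
    """Check every type invariant; report-only, never raises."""
    rep = ValidationReport()
    names = model.names
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        rep.error(dupes[0], "unique-names", f"duplicate group names: {dupes}")

    det_names = set(model.detritus_names)
    for i, g in enumerate(model.groups):
        if g.category not in CATEGORIES:
            rep.error(g.name, "category", f"unknown category {g.category!r}")
            continue
        for attr in ("biomass", "pb", "qb", "catch", "imports"):
            v = getattr(g, attr)
            if v is not None and v < 0:
                rep.error(g.name, "nonnegative", f"{attr} = {v} < 0")
        if not 0.0 <= g.gs <= 1.0:
            rep.error(g.name, "gs-range", f"gs = {g.gs} outside [0, 1]")
        unknowns = g.unknowns()
        if g.category == CONSUMER:
            if len(unknowns) > 1:
                rep.error(g.name, "one-unknown",
                          f"more than one unknown parameter: {unknowns}")
            if g.gs == 0.0:
                rep.warn(g.name, "gs-zero",
                         "consumer with zero unassimilated fraction")
            if g.ee is not None and g.ee > 1.0:
                rep.warn(g.name, "ee-above-one",
                         f"supplied EE = {g.ee} exceeds 1")
            row = model.diet[i]
            if np.any(row < 0):
                rep.error(g.name, "diet-nonnegative",
                          "negative diet fraction")
            s = float(row.sum())
            if abs(s - 1.0) > DIET_TOL:
                rep.error(g.name, "diet-sum",
                          f"diet row sums to {s:.6f}, expected 1")
        else:
            if g.qb != 0.0:  # None (unknown) is not allowed either
                rep.error(g.name, "no-consumption",
                          f"{g.category} must have qb = 0")
            if g.gs != 0.0:
                rep.error(g.name, "no-egestion",
                          f"{g.category} must have gs = 0")
            if np.any(model.diet[i] != 0.0):
                rep.error(g.name, "no-diet",
                          f"{g.category} must have an all-zero diet row")
            if g.category == DETRITUS:
                if g.pb not in (0.0,):
                    rep.error(g.name, "detritus-rates", "detritus must have pb = 0")
            else:  # producer
                if len([p for p in ("biomass", "pb", "ee") if getattr(g, p) is None]) > 1:
                    rep.error(g.name, "one-unknown",
                              "more than one unknown parameter")
        if g.imports and g.category != DETRITUS:
            rep.error(g.name, "import-on-detritus",
                      "imports are only allowed on detritus-type groups "
                      "(model feed-like inputs as detritus pools)")
        fate_sum = 0.0
        for dname, frac in g.detritus_fate.items():
            if dname not in det_names:
                rep.error(g.name, "fate-target",
                          f"fate target {dname!r} is not a detritus group")
            if frac < 0:
                rep.error(g.name, "fate-nonnegative",
                          f"fate fraction for {dname} = {frac} < 0")
            fate_sum += frac
        if fate_sum > 1.0 + DIET_TOL:
            rep.error(g.name, "fate-sum",
                      f"detritus fate fractions sum to {fate_sum:.6f} > 1")
        if g.surplus_disposition not in (SURPLUS_EXPORT, SURPLUS_ACCUMULATION):
            rep.error(g.name, "surplus-disposition",
                      f"unknown disposition {g.surplus_disposition!r}")
    return rep


# ---------------------------------------------------------------------------
# I/O

def _fmt(v: float | None) -> str:
    if v is None:
        return ""
    return format(float(v), ".12g")


def _parse_cell(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, str):
        v = v.strip()
        if v == "" or v.lower() == "unknown":
            return None
    return float(v)


def write_model(model: EcopathModel, path: str, format: str = "csv") -> None:
    """Serialize a model.

    ``csv`` writes a directory holding ``groups.csv`` and ``diet.csv``
    (prey rows, predator columns); ``json`` writes a single file
    mirroring the in-memory structure.  Numeric values keep 12
    significant digits so a round trip is lossless at 1e-9 relative.
    """
    if format == "csv":
        os.makedirs(path, exist_ok=True)
        det = model.detritus_names
        cols = _GROUP_COLUMNS + [f"fate_{d}" for d in det]
        rows = []
        for g in model.groups:
            row = {
                "name": g.name, "category": g.category,
                "biomass": _fmt(g.biomass), "pb": _fmt(g.pb),
                "qb": _fmt(g.qb), "ee": _fmt(g.ee), "gs": _fmt(g.gs),
                "catch": _fmt(g.catch), "import": _fmt(g.imports),
                "ba": _fmt(g.ba), "migration": _fmt(g.migration),
                "surplus_disposition": g.surplus_disposition,
            }
            for d in det:
                row[f"fate_{d}"] = _fmt(g.detritus_fate.get(d, 0.0))
            rows.append(row)
        pd.DataFrame(rows, columns=cols).to_csv(
            os.path.join(path, "groups.csv"), index=False)
        diet = model.diet_frame().map(lambda v: f"{v:.12g}")
        diet.to_csv(os.path.join(path, "diet.csv"),
                    index_label="prey\\predator")
        meta = {"label": model.label, "period_days": model.period_days}
        with open(os.path.join(path, "meta.json"), "w") as fh:
            json.dump(meta, fh, indent=1)
    elif format == "json":
        payload = {
            "label": model.label,
            "period_days": model.period_days,
            "groups": [
                {
                    "name": g.name, "category": g.category,
                    "biomass": g.biomass, "pb": g.pb, "qb": g.qb,
                    "ee": g.ee, "gs": g.gs, "catch": g.catch,
                    "import": g.imports, "ba": g.ba,
                    "migration": g.migration,
                    "surplus_disposition": g.surplus_disposition,
                    "detritus_fate": g.detritus_fate,
                }
                for g in model.groups
            ],
            "diet": {
                model.names[j]: {
                    model.names[i]: model.diet[j, i]
                    for i in range(model.n) if model.diet[j, i] != 0.0
                }
                for j in range(model.n) if model.diet[j].any()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ModelError(f"unknown format {format!r}")


def _load_csv(path: str) -> EcopathModel:
    gpath = os.path.join(path, "groups.csv")
    dpath = os.path.join(path, "diet.csv")
    try:
        gdf = pd.read_csv(gpath, comment="#", dtype=str,
                          skip_blank_lines=True)
    except Exception as exc:
        raise ModelError(f"cannot parse {gpath}: {exc}") from exc
    for col in ("name", "category"):
        if col not in gdf.columns:
            raise ModelError(f"{gpath}: missing required column {col!r}")
    fate_cols = [c for c in gdf.columns if c.startswith("fate_")]
    groups = []
    for irow, rec in gdf.iterrows():
        try:
            fate = {}
            for c in fate_cols:
                v = _parse_cell(rec.get(c))
                if v:
                    fate[c[len("fate_"):]] = v
            kwargs = {k: _parse_cell(rec.get(k)) for k in
                      ("biomass", "pb", "qb", "ee")}
            g = Group(
                name=str(rec["name"]).strip(),
                category=str(rec["category"]).strip(),
                gs=_parse_cell(rec.get("gs")) or 0.0,
                catch=_parse_cell(rec.get("catch")) or 0.0,
                imports=_parse_cell(rec.get("import")) or 0.0,
                ba=_parse_cell(rec.get("ba")) or 0.0,
                migration=_parse_cell(rec.get("migration")) or 0.0,
                detritus_fate=fate,
                surplus_disposition=(str(rec.get("surplus_disposition"))
                                     if isinstance(rec.get("surplus_disposition"), str)
                                     and rec.get("surplus_disposition").strip()
                                     else SURPLUS_EXPORT),
                **kwargs,
            )
        except (TypeError, ValueError) as exc:
            raise ModelError(
                f"{gpath} row {irow + 2}: {exc}") from exc
        groups.append(g)
    try:
        ddf = pd.read_csv(dpath, comment="#", index_col=0)
    except Exception as exc:
        raise ModelError(f"cannot parse {dpath}: {exc}") from exc
    names = [g.name for g in groups]
    ddf.index = [str(x).strip() for x in ddf.index]
    ddf.columns = [str(x).strip() for x in ddf.columns]
    missing = [n for n in names if n not in ddf.index or n not in ddf.columns]
    if missing:
        raise ModelError(f"{dpath}: rows/columns missing for {missing}")
    diet = ddf.loc[names, names].to_numpy(dtype=float).T  # predator-major
    diet = np.nan_to_num(diet)
    period, label = 300, os.path.basename(os.path.normpath(path))
    mpath = os.path.join(path, "meta.json")
    if os.path.exists(mpath):
        with open(mpath) as fh:
            meta = json.load(fh)
        period = meta.get("period_days", period)
        label = meta.get("label", label)
    return EcopathModel(groups, diet, period, label)


def _load_json(source: str) -> EcopathModel:
    try:
        if os.path.exists(source):
            with open(source) as fh:
                payload = json.load(fh)
        else:
            payload = json.loads(source)
    except json.JSONDecodeError as exc:
        raise ModelError(f"cannot parse JSON model: {exc}") from exc
    groups = []
    for rec in payload["groups"]:
        rec = dict(rec)
        rec["imports"] = rec.pop("import", 0.0) or 0.0
        rec.setdefault("surplus_disposition", SURPLUS_EXPORT)
        groups.append(Group(**rec))
    names = [g.name for g in groups]
    diet = np.zeros((len(names), len(names)))
    for pred, row in payload.get("diet", {}).items():
        for prey, frac in row.items():
            diet[names.index(pred), names.index(prey)] = frac
    return EcopathModel(groups, diet, payload.get("period_days", 300),
                        payload.get("label", ""))


def load_model(source: str, format: str | None = None) -> EcopathModel:
    """Read a model from a CSV directory or a JSON file and validate it.

    Raises :class:`ModelError` naming the offending row/column on a parse
    failure, or the first violated invariant on a validation failure.
    """
    if format is None:
        format = "csv" if os.path.isdir(source) else "json"
    if format == "csv":
        model = _load_csv(source)
    elif format == "json":
        model = _load_json(source)
    else:
        raise ModelError(f"unknown format {format!r}")
    validate(model).raise_if_failed()
    return model
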