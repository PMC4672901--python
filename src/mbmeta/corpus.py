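"""Data model and CSV I/O for the systematic-review experiment corpus.

Each record summarises one published T-maze experiment: an experimental
arm and a control arm, each with an iteration count and (optionally) a
mean Performance Index (PI) with its SEM, plus the design moderators
carried through to the meta-regression stage.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Callable, Iterable, Iterator, Optional

__all__ = [
    "ExperimentRecord",
    "Dataset",
    "ValidationError",
    "ClassificationError",
    "INTERVENTIONS",
    "LOBE_CATEGORIES",
    "CURRENT_TYPES",
    "load_dataset",
    "write_dataset",
    "table1_fixture",
    "summarize_counts",
    "assign_lobe_category",
    "assign_shared_controls",
    "rut_mutant_subgroup",
    "heat_control_subgroup",
    "column_schema",
]

INTERVENTIONS = ("rut_rescue", "rut_mutant", "shi_inactivation", "heat_control")
LOBE_CATEGORIES = (
    "alphabeta",
    "alphaprime_betaprime",
    "gamma",
    "alphabeta_gamma",
    "all_lobes",
    "none",
)
CURRENT_TYPES = ("AC", "DC", "unknown")

RUT_INTERVENTIONS = ("rut_rescue", "rut_mutant")
SHI_INTERVENTIONS = ("shi_inactivation", "heat_control")


class ValidationError(ValueError):
    """Raised when a record or dataset violates the schema invariants."""

    def __init__(self, failures: list[str]):
        self.failures = list(failures)
        super().__init__("; ".join(self.failures))


class ClassificationError(ValueError):
    """Raised when a record cannot be assigned a lobe category."""


@dataclass(frozen=True)
class ExperimentRecord:
    """One row of the review dataset (one published experiment)."""

    study_id: str
    figure_panel: str
    genotype_exp: str
    genotype_ctrl: str
    n_exp: int
    n_ctrl: int
    pi_exp_mean: Optional[float] = None
    pi_exp_sem: Optional[float] = None
    pi_ctrl_mean: Optional[float] = None
    pi_ctrl_sem: Optional[float] = None
    intervention: str = "rut_rescue"
    lobe_category: str = "none"
    driver: Optional[str] = None
    odor_pair: str = ""
    benzaldehyde: bool = False
    temperature_c: Optional[float] = None
    shock_v: Optional[float] = None
    current_type: str = "unknown"
    delay_min: float = 0.0
    rh_pct: Optional[float] = None
    shared_control_id: Optional[str] = None

    @property
    def key(self) -> tuple:
        return (
            self.study_id,
            self.figure_panel,
            self.genotype_exp,
            self.genotype_ctrl,
            self.lobe_category,
        )

    def validation_failures(self) -> list[str]:
        fails = []
        if self.n_exp < 1:
            fails.append(f"n_exp must be >= 1, got {self.n_exp}")
        if self.n_ctrl < 1:
            fails.append(f"n_ctrl must be >= 1, got {self.n_ctrl}")
        for name in ("pi_exp_mean", "pi_ctrl_mean"):
            v = getattr(self, name)
            if v is not None and not -1.0 <= v <= 1.0:
                fails.append(f"{name} must lie in [-1, 1], got {v}")
        for name in ("pi_exp_sem", "pi_ctrl_sem"):
            v = getattr(self, name)
            if v is not None and v < 0:
                fails.append(f"{name} must be >= 0, got {v}")
        if self.intervention not in INTERVENTIONS:
            fails.append(f"unknown intervention {self.intervention!r}")
        if self.lobe_category not in LOBE_CATEGORIES:
            fails.append(f"unknown lobe_category {self.lobe_category!r}")
        if self.current_type not in CURRENT_TYPES:
            fails.append(f"unknown current_type {self.current_type!r}")
        if self.delay_min < 0:
            fails.append(f"delay_min must be >= 0, got {self.delay_min}")
        expects_ben = "BEN" in self.odor_pair.upper()
        if self.benzaldehyde != expects_ben:
            fails.append(
                f"benzaldehyde={self.benzaldehyde} inconsistent with "
                f"odor_pair {self.odor_pair!r}"
            )
        if self.lobe_category == "none" and self.intervention not in (
            "rut_mutant",
            "heat_control",
        ):
            fails.append(
                f"lobe_category 'none' not allowed for {self.intervention}"
            )
        return [f"{self.study_id}/{self.figure_panel}/{self.genotype_exp}: {f}" for f in fails]


@dataclass
class Dataset:
    """An ordered, validated collection of experiment records."""

    records: list[ExperimentRecord] = field(default_factory=list)
    provenance: str = "<memory>"

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ExperimentRecord]:
        return iter(self.records)

    def validate(self) -> None:
        fails: list[str] = []
        seen: dict[tuple, int] = {}
        for i, r in enumerate(self.records):
            fails.extend(r.validation_failures())
            if r.key in seen:
                fails.append(
                    f"duplicate record key {r.key} (rows {seen[r.key]} and {i})"
                )
            else:
                seen[r.key] = i
        blocks: dict[str, ExperimentRecord] = {}
        for r in self.records:
            if r.shared_control_id is None:
                continue
            first = blocks.setdefault(r.shared_control_id, r)
            if (first.study_id, first.genotype_ctrl) != (r.study_id, r.genotype_ctrl):
                fails.append(
                    f"shared_control_id {r.shared_control_id!r} spans "
                    f"inconsistent study/control genotypes"
                )
        if fails:
            raise ValidationError(fails)

    def filter(self, pred: Callable[[ExperimentRecord], bool]) -> "Dataset":
        return Dataset(
            [r for r in self.records if pred(r)],
            provenance=f"{self.provenance}[filtered]",
        )

    def rut_records(self) -> "Dataset":
        return self.filter(lambda r: r.intervention in RUT_INTERVENTIONS)

    def shi_records(self) -> "Dataset":
        return self.filter(lambda r: r.intervention in SHI_INTERVENTIONS)


_COLUMNS = [f.name for f in fields(ExperimentRecord)]

_FLOAT_OPTIONAL = {
    "pi_exp_mean",
    "pi_exp_sem",
    "pi_ctrl_mean",
    "pi_ctrl_sem",
    "temperature_c",
    "shock_v",
    "rh_pct",
}
_TEXT_OPTIONAL = {"driver", "shared_control_id"}


def _parse_cell(name: str, raw: str):
    raw = raw.strip()
    if name in ("n_exp", "n_ctrl"):
        return int(raw)
    if name in _FLOAT_OPTIONAL:
        if raw in ("", "-"):
            return None
        if "–" in raw or ("-" in raw[1:]):  # range like "21-25" -> midpoint
            sep = "–" if "–" in raw else "-"
            lo, hi = raw.split(sep, 1)
            return (float(lo) + float(hi)) / 2.0
        return float(raw)
    if name == "delay_min":
        if raw in ("0*", "immediately"):
            return 0.0
        return float(raw)
    if name == "benzaldehyde":
        return raw.lower() in ("true", "1", "yes")
    if name in _TEXT_OPTIONAL:
        return raw if raw not in ("", "-") else None
    return raw


def load_dataset(source, provenance: Optional[str] = None) -> Dataset:
    """Read a corpus CSV (path or text file handle) into a ``Dataset``.

    Empty cells and ``-`` are missing values; temperature/RH ranges such
    as ``21-25`` collapse to their midpoint; a delay of ``0*`` codes the
    "immediately tested" experiments as 0 minutes.
    """
    if hasattr(source, "read"):
        fh = source
        name = provenance or getattr(source, "name", "<stream>")
        return _load_from_handle(fh, name)
    with open(source, newline="", encoding="utf-8") as fh:
        return _load_from_handle(fh, provenance or str(source))


def _load_from_handle(fh, provenance: str) -> Dataset:
    reader = csv.DictReader(fh)
    header = reader.fieldnames or []
    missing = [c for c in _COLUMNS if c not in header]
    if missing:
        raise ValidationError([f"missing column(s): {', '.join(missing)}"])
    records = []
    for lineno, row in enumerate(reader, start=2):
        kwargs = {}
        for name in _COLUMNS:
            try:
                kwargs[name] = _parse_cell(name, row[name] or "")
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    [f"row {lineno}, column {name!r}: cannot parse {row[name]!r} ({exc})"]
                ) from exc
        records.append(ExperimentRecord(**kwargs))
    return Dataset(records, provenance=provenance)


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and value == int(value):
        return str(value)
    return str(value)


def write_dataset(ds: Dataset, target) -> None:
    """Write a dataset back to CSV (inverse of :func:`load_dataset`)."""
    if hasattr(target, "write"):
        _write_to_handle(ds, target)
    else:
        with open(target, "w", newline="", encoding="utf-8") as fh:
            _write_to_handle(ds, fh)


def _write_to_handle(ds: Dataset, fh) -> None:
    writer = csv.writer(fh)
    writer.writerow(_COLUMNS)
    for r in ds.records:
        writer.writerow([_format_cell(getattr(r, c)) for c in _COLUMNS])


def table1_fixture() -> Dataset:
    """Return the packaged transcription of the review's experiment table.

    PI means/SEMs are absent (the printed table reports iteration counts
    and moderators only); shared-control ids follow the grouping rule in
    :func:`assign_shared_controls`.
    """
    text = resources.files("mbmeta.data").joinpath("table1.csv").read_text("utf-8")
    return _load_from_handle(io.StringIO(text), provenance="table1_fixture")


def summarize_counts(
    ds: Dataset, pred: Optional[Callable[[ExperimentRecord], bool]] = None
) -> dict:
    """Row and iteration totals over the records matching ``pred``."""
    matched = [r for r in ds.records if pred is None or pred(r)]
    return {
        "rows": len(matched),
        "sum_n_exp": sum(r.n_exp for r in matched),
        "sum_n_ctrl": sum(r.n_ctrl for r in matched),
    }


def assign_lobe_category(r: ExperimentRecord, reassign_201Y: bool = False) -> str:
    """Record's lobe category, optionally moving the 201Y driver.

    The primary classification counts 201Y as a gamma-lobe driver; the
    variant reassigns it to the alphabeta_gamma combination.
    """
    if r.lobe_category == "none" and r.intervention not in ("rut_mutant", "heat_control"):
        raise ClassificationError(
            f"no lobe category for {r.study_id}/{r.figure_panel}/{r.genotype_exp}"
        )
    if reassign_201Y and r.driver == "201Y" and r.lobe_category == "gamma":
        return "alphabeta_gamma"
    return r.lobe_category


def assign_shared_controls(ds: Dataset) -> Dataset:
    """Assign shared-control ids by the deterministic grouping rule.

    Rutabaga-intervention records within the same study and figure panel
    whose control genotype and control iteration count coincide are
    treated as sharing one control arm; groups of size >= 2 receive a
    common id, singletons stay unlinked.
    """
    groups: dict[tuple, list[int]] = {}
    for i, r in enumerate(ds.records):
        if r.intervention in RUT_INTERVENTIONS:
            key = (r.study_id, r.figure_panel, r.genotype_ctrl, r.n_ctrl)
            groups.setdefault(key, []).append(i)
    assignment: dict[int, str] = {}
    counter = 0
    for key in sorted(groups):
        members = groups[key]
        if len(members) >= 2:
            counter += 1
            for i in members:
                assignment[i] = f"SC{counter:02d}"
    records = [
        replace(r, shared_control_id=assignment.get(i))
        if r.intervention in RUT_INTERVENTIONS
        else r
        for i, r in enumerate(ds.records)
    ]
    return Dataset(records, provenance=f"{ds.provenance}[shared-controls]")


def rut_mutant_subgroup(r: ExperimentRecord) -> str:
    """Genotype subgroup label for a rut-hypomorph (non-rescue) record."""
    if r.intervention != "rut_mutant":
        raise ValueError(f"not a rut_mutant record: {r.genotype_exp}")
    allele = "rut1" if "rut1" in r.genotype_exp else "rut2080"
    if "UAS-rut" in r.genotype_exp:
        return f"{allele}; UAS-rut"
    if r.driver:
        return f"{allele} w/ driver"
    return allele


def heat_control_subgroup(r: ExperimentRecord) -> str:
    """Control-genotype class for a heat-effect control record."""
    if r.intervention != "heat_control":
        raise ValueError(f"not a heat_control record: {r.genotype_exp}")
    if "UAS-shi" in r.genotype_exp or r.genotype_exp.startswith("shi-"):
        return "UAS-shi/+"
    if r.driver:
        return "driver/+"
    return "wild type"


def column_schema() -> dict:
    """JSON-serialisable description of the corpus CSV columns."""
    text = resources.files("mbmeta.data").joinpath("schema.json").read_text("utf-8")
    return json.loads(text)
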