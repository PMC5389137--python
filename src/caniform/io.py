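"""Reading, validating and merging 3D landmark data.

Two on-disk dialects are supported: the TPS exchange format (``LM3=``,
``ID=``, optional ``SCALE=`` records) and a tabular long format with one
row per landmark (columns ``specimen_id, group, role, view, replicate,
landmark, x, y, z``).  All coordinates are treated as millimetres.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

GROUPS = ("dog", "arctic_wolf", "eurasian_wolf", "unknown")
VIEWS = ("dorsal", "ventral", "combined")
WOLF_GROUPS = ("arctic_wolf", "eurasian_wolf")


class LandmarkError(ValueError):
    """Raised for malformed or inconsistent landmark data."""


@dataclass
class LandmarkConfiguration:
    """One digitization of one specimen view: K labelled 3D points (mm)."""

    specimen_id: str
    view: str
    replicate: int
    labels: list[str]
    coords: np.ndarray  # (K, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.view not in VIEWS:
            raise LandmarkError(f"unknown view {self.view!r}")
        if self.replicate < 1:
            raise LandmarkError("replicate must be >= 1")
        if self.coords.shape != (len(self.labels), 3):
            raise LandmarkError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise LandmarkError(f"duplicate landmark labels in {self.specimen_id}")
        if not np.all(np.isfinite(self.coords)):
            raise LandmarkError(f"non-finite coordinate in {self.specimen_id}")

    @property
    def k(self) -> int:
        return len(self.labels)

    def subset(self, labels: Sequence[str]) -> np.ndarray:
        """Coordinates of ``labels`` in the given order."""
        idx = [self.labels.index(l) for l in labels]
        return self.coords[idx]

    def reordered(self, labels: Sequence[str]) -> "LandmarkConfiguration":
        idx = [self.labels.index(l) for l in labels]
        return replace(self, labels=list(labels), coords=self.coords[idx].copy())


@dataclass
class SymmetryMap:
    """Bilateral structure of a configuration: left/right pairs plus midline."""

    pairs: list[tuple[str, str]]
    midline: list[str]

    def all_labels(self) -> list[str]:
        out: list[str] = []
        for l, r in self.pairs:
            out.extend((l, r))
        out.extend(self.midline)
        return out

    def validate(self) -> None:
        labels = self.all_labels()
        if len(set(labels)) != len(labels):
            raise LandmarkError("symmetry map lists a label twice")

    def covers(self, labels: Iterable[str]) -> list[str]:
        """Labels in ``labels`` missing from this map."""
        have = set(self.all_labels())
        return [l for l in labels if l not in have]

    def swap_permutation(self, labels: Sequence[str]) -> np.ndarray:
        """Row permutation exchanging left and right landmarks."""
        swap = {l: r for l, r in self.pairs}
        swap.update({r: l for l, r in self.pairs})
        index = {lab: i for i, lab in enumerate(labels)}
        return np.array([index[swap.get(lab, lab)] for lab in labels])


@dataclass
class Specimen:
    id: str
    group: str
    role: str  # reference | projected
    configurations: list[LandmarkConfiguration] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise LandmarkError(f"unknown group {self.group!r}")
        if self.role not in ("reference", "projected"):
            raise LandmarkError(f"unknown role {self.role!r}")
        if self.role == "reference" and self.group == "unknown":
            raise LandmarkError(f"specimen {self.id}: unknowns must be projected")

    def combined(self) -> list[LandmarkConfiguration]:
        return [c for c in self.configurations if c.view == "combined"]


@dataclass
class Dataset:
    specimens: list[Specimen]
    symmetry: SymmetryMap

    def __post_init__(self) -> None:
        ids = [s.id for s in self.specimens]
        if len(set(ids)) != len(ids):
            raise LandmarkError("duplicate specimen ids")

    def references(self) -> list[Specimen]:
        return [s for s in self.specimens if s.role == "reference"]

    def projected(self) -> list[Specimen]:
        return [s for s in self.specimens if s.role == "projected"]


# ---------------------------------------------------------------------------
# TPS dialect

def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a 3D TPS file (LM3=/ID=/SCALE= records) into configurations.

    Metadata not expressible in TPS (view, replicate, group) defaults to
    ``combined`` / replicate 1; the ID field carries the specimen id.
    """
    records: list[LandmarkConfiguration] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM3"):
            raise LandmarkError(f"{path}:{i + 1}: expected LM3= record, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except (IndexError, ValueError):
            raise LandmarkError(f"{path}:{i + 1}: malformed LM3 record {line!r}")
        coords = np.empty((k, 3))
        for j in range(k):
            row = lines[i + 1 + j].split()
            if len(row) != 3:
                raise LandmarkError(f"{path}:{i + 2 + j}: expected 3 coordinates")
            try:
                coords[j] = [float(v) for v in row]
            except ValueError:
                raise LandmarkError(f"{path}:{i + 2 + j}: non-numeric coordinate")
        i += 1 + k
        spec_id = f"record_{len(records) + 1}"
        scale = None
        while i < len(lines) and lines[i].strip() and "=" in lines[i] and not lines[i].upper().startswith("LM3"):
            key, _, val = lines[i].strip().partition("=")
            key = key.strip().upper()
            if key == "ID":
                spec_id = val.strip()
            elif key == "SCALE":
                scale = float(val)
            i += 1
        if scale is not None:
            coords = coords * scale
        labels = [f"L{j + 1}" for j in range(k)]
        records.append(
            LandmarkConfiguration(spec_id, "combined", 1, labels, coords)
        )
    return records


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM3={c.k}\n")
            for x, y, z in c.coords:
                fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")
            fh.write(f"ID={c.specimen_id}\n")


# ---------------------------------------------------------------------------
# Tabular long format

TABLE_COLUMNS = [
    "specimen_id", "group", "role", "view", "replicate", "landmark", "x", "y", "z",
]


def read_table(path: str | Path) -> tuple[list[LandmarkConfiguration], dict[str, tuple[str, str]]]:
    """Read the long tabular dialect.

    Returns the configurations plus a map specimen_id -> (group, role) so a
    caller can assemble :class:`Specimen` objects.
    """
    path = Path(path)
    delim = "\t" if "\t" in path.read_text(encoding="utf-8")[:2048] else ","
    groups: dict[str, tuple[str, str]] = {}
    rows: dict[tuple[str, str, int], tuple[list[str], list[list[float]]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        missing = [c for c in TABLE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise LandmarkError(f"{path}: missing columns {missing}")
        for ln, row in enumerate(reader, start=2):
            key = (row["specimen_id"], row["view"], int(row["replicate"]))
            groups[row["specimen_id"]] = (row["group"], row["role"])
            labels, coords = rows.setdefault(key, ([], []))
            labels.append(row["landmark"])
            try:
                coords.append([float(row[a]) for a in "xyz"])
            except ValueError:
                raise LandmarkError(f"{path}:{ln}: non-numeric coordinate")
    configs = [
        LandmarkConfiguration(sid, view, rep, labels, np.array(coords))
        for (sid, view, rep), (labels, coords) in rows.items()
    ]
    return configs, groups


def write_table(dataset: Dataset, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(TABLE_COLUMNS)
        for sp in dataset.specimens:
            for c in sp.configurations:
                for lab, (x, y, z) in zip(c.labels, c.coords):
                    w.writerow(
                        [sp.id, sp.group, sp.role, c.view, c.replicate, lab,
                         f"{x:.12g}", f"{y:.12g}", f"{z:.12g}"]
                    )


def read_dataset(path: str | Path, symmetry: SymmetryMap) -> Dataset:
    """Assemble a Dataset from a long-format table file."""
    configs, meta = read_table(path)
    by_spec: dict[str, list[LandmarkConfiguration]] = {}
    for c in configs:
        by_spec.setdefault(c.specimen_id, []).append(c)
    specimens = [
        Specimen(sid, meta[sid][0], meta[sid][1], cfgs)
        for sid, cfgs in by_spec.items()
    ]
    return Dataset(specimens, symmetry)


def read_landmarks(path: str | Path, dialect: str) -> list[LandmarkConfiguration]:
    """Dispatch to the TPS or table reader; returns bare configurations."""
    if dialect == "tps":
        return read_tps(path)
    if dialect == "table":
        return read_table(path)[0]
    raise LandmarkError(f"unsupported dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Config file (symmetry map + measurement scheme + run parameters)

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise LandmarkError(f"{path}: config must be a mapping")
    return cfg


def symmetry_from_config(cfg: dict) -> SymmetryMap:
    sym = cfg.get("symmetry", cfg)
    pairs = [tuple(p) for p in sym.get("pairs", [])]
    mid = list(sym.get("midline", []))
    out = SymmetryMap(pairs, mid)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# View merging

def merge_views(
    dorsal: LandmarkConfiguration,
    ventral: LandmarkConfiguration,
    matching_labels: Sequence[str],
) -> LandmarkConfiguration:
    """Rigidly fit the ventral view onto the dorsal one and take the union.

    The ventral configuration is rotated (proper rotation, det = +1) and
    translated — never scaled or reflected — so the summed squared distance
    between the shared landmarks is minimal; the shared landmarks are then
    replaced by the midpoint of each fitted pair, so the combined
    configuration has a fixed landmark count.
    """
    from .procrustes import rigid_fit  # local import to avoid a cycle

    for lab in matching_labels:
        if lab not in dorsal.labels or lab not in ventral.labels:
            raise LandmarkError(f"matching landmark {lab!r} missing from a view")
    overlap = (set(dorsal.labels) & set(ventral.labels)) - set(matching_labels)
    if overlap:
        raise LandmarkError(f"views share unexpected labels {sorted(overlap)}")

    a = ventral.subset(matching_labels)
    b = dorsal.subset(matching_labels)
    rot, trans, _ = rigid_fit(a, b)
    moved = ventral.coords @ rot + trans

    labels = list(dorsal.labels)
    coords = [dorsal.coords.copy()]
    fitted = dict(zip(ventral.labels, moved))
    extra_labels = [l for l in ventral.labels if l not in matching_labels]
    labels.extend(extra_labels)
    coords.append(np.array([fitted[l] for l in extra_labels]))
    merged = np.vstack(coords)
    for lab in matching_labels:
        i = labels.index(lab)
        merged[i] = 0.5 * (dorsal.subset([lab])[0] + fitted[lab])
    return LandmarkConfiguration(
        dorsal.specimen_id, "combined", dorsal.replicate, labels, merged
    )


# ---------------------------------------------------------------------------
# Validation

@dataclass
class Finding:
    severity: str  # fatal | warning
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def fatal(self) -> bool:
        return any(f.severity == "fatal" for f in self.findings)

    def add(self, severity: str, message: str) -> None:
        self.findings.append(Finding(severity, message))


def validate_dataset(d: Dataset) -> ValidationReport:
    """Report structural problems; the pipeline refuses to run on fatal ones."""
    report = ValidationReport()
    if not d.specimens or not any(s.configurations for s in d.specimens):
        report.add("fatal", "no configurations present")
        return report

    def replicate_unions(s: Specimen) -> dict[int, set[str]]:
        # label set per replicate: combined configs if present, otherwise
        # the union over that replicate's views
        cfgs = s.combined() or s.configurations
        out: dict[int, set[str]] = {}
        for c in cfgs:
            out.setdefault(c.replicate, set()).update(c.labels)
        return out

    ref_labels = set.union(*replicate_unions(d.specimens[0]).values())
    for sp in d.specimens:
        for rep, labels in replicate_unions(sp).items():
            for lab in sorted(ref_labels - labels):
                report.add(
                    "fatal",
                    f"specimen {sp.id} replicate {rep}: missing landmark {lab!r}",
                )
            for lab in sorted(labels - ref_labels):
                report.add(
                    "fatal",
                    f"specimen {sp.id} replicate {rep}: unexpected landmark {lab!r}",
                )
    for lab in d.symmetry.covers(sorted(ref_labels)):
        report.add("fatal", f"symmetry map does not cover landmark {lab!r}")
    try:
        d.symmetry.validate()
    except LandmarkError as e:
        report.add("fatal", str(e))
    counts = {
        s.id: len(s.combined()) or len({c.replicate for c in s.configurations})
        for s in d.specimens
    }
    modal = max(set(counts.values()), key=list(counts.values()).count)
    for sid, n in counts.items():
        if n != modal:
            report.add(
                "warning",
                f"specimen {sid}: {n} replicates (most specimens have {modal})",
            )
    return report
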