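"""Cell bags, slide records, cohort I/O, patient-level splits and composition vectors.

A *bag* is one slide's matrix of per-cell feature embeddings (one row per
white blood cell, as produced by a frozen cell-image encoder). Slide-level
diagnosis labels attach to bags, never to cells — the multiple-instance
setting. Cohorts are exchanged as a CSV manifest plus one CSV embedding
matrix per slide, so fixtures stay human-inspectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CLASSES",
    "DEFAULT_CELL_TYPES",
    "CellBag",
    "SlideRecord",
    "CohortSplit",
    "CompositionVector",
    "load_cohort",
    "save_cohort",
    "split_by_patient",
    "composition_vector",
]

DEFAULT_CLASSES = ("AL", "MDS", "HCL", "NL")

# 23 hematopoietic cell classes, mirroring the granularity of a
# marrow-trained single-cell classifier's label space.
DEFAULT_CELL_TYPES = (
    "blast",
    "promyelocyte",
    "myelocyte",
    "metamyelocyte",
    "band_neutrophil",
    "segmented_neutrophil",
    "eosinophil",
    "basophil",
    "monocyte",
    "lymphocyte",
    "atypical_lymphocyte",
    "plasma_cell",
    "proerythroblast",
    "basophilic_erythroblast",
    "polychromatophilic_erythroblast",
    "orthochromic_erythroblast",
    "megakaryocyte_nucleus",
    "mitotic_body",
    "smudge_cell",
    "giant_platelet",
    "platelet_clump",
    "nucleated_rbc_other",
    "unidentifiable",
)


class CohortError(ValueError):
    """Inconsistent cohort (e.g. embedding dimension mismatch across slides)."""


@dataclass
class CellBag:
    """One slide's N x D embedding matrix with optional per-cell annotations."""

    slide_id: str
    embeddings: np.ndarray
    cell_types: Optional[Sequence[str]] = None
    cell_refs: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] < 1:
            raise ValueError(f"bag {self.slide_id!r}: embeddings must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.embeddings)):
            bad = int(np.argwhere(~np.isfinite(self.embeddings))[0][0])
            raise ValueError(f"bag {self.slide_id!r}: non-finite embedding value at row {bad}")
        if self.cell_types is not None:
            self.cell_types = list(self.cell_types)
            if len(self.cell_types) != self.n_cells:
                raise ValueError(
                    f"bag {self.slide_id!r}: {len(self.cell_types)} cell_types for "
                    f"{self.n_cells} cells"
                )
        if self.cell_refs is not None:
            self.cell_refs = list(self.cell_refs)
            if len(self.cell_refs) != self.n_cells:
                raise ValueError(f"bag {self.slide_id!r}: cell_refs length mismatch")

    @property
    def n_cells(self) -> int:
        return self.embeddings.shape[0]

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]


@dataclass
class SlideRecord:
    """A labeled bag: the unit of (weak) supervision."""

    bag: CellBag
    patient_id: str
    label: str
    blast_fraction: Optional[float] = None
    classes: Sequence[str] = DEFAULT_CLASSES

    def __post_init__(self):
        if self.label not in self.classes:
            raise ValueError(
                f"slide {self.bag.slide_id!r}: label {self.label!r} not in class set {tuple(self.classes)}"
            )
        if self.blast_fraction is not None:
            if isinstance(self.blast_fraction, str):
                raise ValueError("blast_fraction must be numeric in [0,1], not a string")
            bf = float(self.blast_fraction)
            if not 0.0 <= bf <= 1.0:
                raise ValueError(
                    f"slide {self.bag.slide_id!r}: blast_fraction {bf} outside [0,1]"
                )
            self.blast_fraction = bf


@dataclass
class CohortSplit:
    train: list
    validation: list
    test: list

    def __post_init__(self):
        groups = [self.train, self.validation, self.test]
        pid_sets = [{r.patient_id for r in g} for g in groups]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = pid_sets[i] & pid_sets[j]
                if overlap:
                    raise ValueError(f"patients {sorted(overlap)} appear in multiple partitions")

    @property
    def all_records(self) -> list:
        return list(self.train) + list(self.validation) + list(self.test)


@dataclass
class CompositionVector:
    """Per-slide cell-type fractions — the classical blood differential."""

    fractions: Mapping[str, float]
    n_cells: int

    def __post_init__(self):
        if self.n_cells > 0:
            total = math.fsum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"fractions sum to {total}, expected 1")

    def as_array(self, vocabulary: Sequence[str]) -> np.ndarray:
        return np.array([self.fractions.get(t, 0.0) for t in vocabulary])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_bag_csv(path: Path, slide_id: str) -> CellBag:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise CohortError(f"slide {slide_id!r}: embedding file not found: {path}") from None
    cell_types = None
    cell_refs = None
    if "cell_type" in df.columns:
        cell_types = df.pop("cell_type").astype(str).tolist()
    if "cell_ref" in df.columns:
        cell_refs = df.pop("cell_ref").astype(str).tolist()
    mat = df.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(mat)):
        bad = int(np.argwhere(~np.isfinite(mat))[0][0])
        raise CohortError(f"slide {slide_id!r}: non-finite embedding at row {bad} of {path}")
    return CellBag(slide_id=slide_id, embeddings=mat, cell_types=cell_types, cell_refs=cell_refs)


def load_cohort(manifest_path, embedding_dir=None,
                classes: Sequence[str] = DEFAULT_CLASSES) -> list:
    """Load SlideRecords from a CSV manifest and its per-slide embedding CSVs.

    The manifest must have columns ``slide_id, patient_id, label,
    embedding_file`` and optionally ``blast_fraction``. Relative
    ``embedding_file`` paths resolve against ``embedding_dir`` (default:
    the manifest's directory).
    """
    manifest_path = Path(manifest_path)
    base = Path(embedding_dir) if embedding_dir is not None else manifest_path.parent
    manifest = pd.read_csv(manifest_path, dtype={"slide_id": str, "patient_id": str})
    required = {"slide_id", "patient_id", "label", "embedding_file"}
    missing = required - set(manifest.columns)
    if missing:
        raise CohortError(f"manifest missing columns: {sorted(missing)}")

    records = []
    dim = None
    for row in manifest.itertuples(index=False):
        bf = getattr(row, "blast_fraction", None)
        if bf is not None:
            if isinstance(bf, str):
                raise CohortError(
                    f"slide {row.slide_id!r}: blast_fraction {bf!r} is not numeric "
                    "(percent strings are rejected; use a fraction in [0,1])"
                )
            bf = None if pd.isna(bf) else float(bf)
        epath = Path(row.embedding_file)
        if not epath.is_absolute():
            epath = base / epath
        bag = _read_bag_csv(epath, str(row.slide_id))
        if dim is None:
            dim = bag.dim
        elif bag.dim != dim:
            raise CohortError(
                f"slide {row.slide_id!r} has embedding dimension {bag.dim}, cohort uses {dim}"
            )
        records.append(SlideRecord(bag=bag, patient_id=str(row.patient_id),
                                   label=str(row.label), blast_fraction=bf, classes=classes))
    return records


def save_cohort(records: Sequence[SlideRecord], out_dir) -> Path:
    """Write a cohort as manifest.csv + one embedding CSV per slide.

    Round-trips through :func:`load_cohort`: matrices to float round-trip
    precision, metadata exactly.
    """
    if not records:
        raise ValueError("cannot save an empty cohort")
    dims = {r.bag.dim for r in records}
    if len(dims) > 1:
        raise CohortError(f"records have mixed embedding dimensions: {sorted(dims)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        bag = rec.bag
        fname = f"{bag.slide_id}.csv"
        df = pd.DataFrame(bag.embeddings, columns=[f"dim_{j}" for j in range(bag.dim)])
        if bag.cell_types is not None:
            df["cell_type"] = bag.cell_types
        if bag.cell_refs is not None:
            df["cell_ref"] = bag.cell_refs
        df.to_csv(out_dir / fname, index=False, float_format="%.17g")
        rows.append({
            "slide_id": bag.slide_id,
            "patient_id": rec.patient_id,
            "label": rec.label,
            "blast_fraction": "" if rec.blast_fraction is None else repr(rec.blast_fraction),
            "embedding_file": fname,
        })
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


# ---------------------------------------------------------------------------
# Splits and composition
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, fractions: Sequence[float]) -> list:
    """Apportion n items to len(fractions) buckets; ties go to earlier buckets."""
    quotas = [f * n for f in fractions]
    counts = [int(math.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    short = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def split_by_patient(records: Sequence[SlideRecord], fractions=(0.6, 0.2, 0.2),
                     seed: int = 0, stratify_by_label: bool = False) -> CohortSplit:
    """Partition slides into train/validation/test at the patient level.

    Every patient's slides land wholly in one partition. Patient counts per
    partition follow largest-remainder rounding over a seed-shuffled patient
    list (patients first sorted by id so the split is a function of the
    patient set, not input order).
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(math.fsum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {math.fsum(fractions)}")

    by_patient: dict = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    if len(by_patient) < 3:
        raise ValueError(f"need at least 3 distinct patients, got {len(by_patient)}")

    rng = np.random.default_rng(seed)

    def assign(patients: list) -> list:
        patients = sorted(patients)
        rng.shuffle(patients)
        n_train, n_val, _ = _largest_remainder(len(patients), fractions)
        part = [0] * n_train + [1] * n_val + [2] * (len(patients) - n_train - n_val)
        return list(zip(patients, part))

    assignments = []
    if stratify_by_label:
        by_label: dict = {}
        for pid, recs in by_patient.items():
            by_label.setdefault(recs[0].label, []).append(pid)
        for label in sorted(by_label):
            assignments.extend(assign(by_label[label]))
    else:
        assignments = assign(list(by_patient))

    parts: list = [[], [], []]
    for pid, p in assignments:
        parts[p].extend(by_patient[pid])
    return CohortSplit(train=parts[0], validation=parts[1], test=parts[2])


def composition_vector(bag: CellBag, vocabulary: Sequence[str] = DEFAULT_CELL_TYPES) -> CompositionVector:
    """Cell-type fractions of a bag — the input of count-only (cytometry) classifiers."""
    if bag.cell_types is None:
        raise ValueError(
            f"bag {bag.slide_id!r} has no cell_types; composition vectors need type-labeled bags"
        )
    vocab = list(vocabulary)
    vocab_set = set(vocab)
    counts = dict.fromkeys(vocab, 0)
    for t in bag.cell_types:
        if t not in vocab_set:
            raise ValueError(f"bag {bag.slide_id!r}: unknown cell type {t!r}")
        counts[t] += 1
    n = bag.n_cells
    from fractions import Fraction
    fracs = {t: Fraction(c, n) for t, c in counts.items()}
    return CompositionVector(fractions={t: float(f) for t, f in fracs.items()}, n_cells=n)
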