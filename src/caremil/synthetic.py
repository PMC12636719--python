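"""Synthetic embedding cohorts with controllable morphology and composition
signals, and the synthetic-patient blast-mixing engine for limit-of-detection
studies.

The generator emulates what a frozen cell-image encoder produces on real
blood smears: cells of one type cluster around a type prototype in embedding
space (isotropic Gaussian noise), and disease manifests as either

* a *composition* shift — more cells of a diagnostic type (e.g. circulating
  blasts in acute leukemia), with unchanged per-cell morphology; or
* a *morphology* shift — a fraction of cells of an existing type move to a
  shifted sub-cluster (e.g. dysplastic neutrophils, hairy lymphocytes) while
  the recorded cell-type label and the blood differential stay unchanged; or
* both.

Recorded ``cell_types`` are truthful unless a marker spec sets
``mislabel_as``, which emulates an encoder mislabeling an abnormal variant
(hairy cells read as monocytes/blasts). Planted marker cells are flagged in
``cell_refs`` so downstream overlap statistics have ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bags import CellBag, SlideRecord

__all__ = ["MarkerSpec", "CellPrototypeSet", "SyntheticCohortConfig",
           "make_prototypes", "sample_bag", "generate_cohort",
           "default_cohort_config", "two_class_config", "marker_flags",
           "extract_pools", "mix_synthetic_patient", "lod_experiment"]

MARKER_REF = "marker"
BACKGROUND_REF = "bg"

# a typical circulating differential: mostly neutrophils and lymphocytes
_NORMAL_DIFFERENTIAL = {
    "segmented_neutrophil": 0.50,
    "band_neutrophil": 0.05,
    "lymphocyte": 0.30,
    "monocyte": 0.08,
    "eosinophil": 0.03,
    "basophil": 0.01,
    "blast": 0.01,
    "plasma_cell": 0.01,
    "mitotic_body": 0.01,
}
DEFAULT_SYNTHETIC_VOCAB = tuple(_NORMAL_DIFFERENTIAL)


@dataclass
class MarkerSpec:
    """How a disease class plants its diagnostic cells.

    ``mode='additive'`` adds marker cells on top of the background
    differential (composition signal); ``mode='in_type'`` morphs a fraction
    of existing ``source_type`` cells in place, leaving the differential
    untouched (morphology-only signal). ``shift_scale=0`` removes the
    morphology signal from an additive marker (composition-only).
    """

    source_type: str
    fraction_range: Tuple[float, float] = (0.1, 0.4)
    shift_scale: float = 1.0
    mode: str = "additive"
    mislabel_as: Optional[str] = None

    def __post_init__(self):
        lo, hi = self.fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"fraction_range must be within [0,1], got {self.fraction_range}")
        if self.mode not in ("additive", "in_type"):
            raise ValueError(f"unknown marker mode {self.mode!r}")


@dataclass
class CellPrototypeSet:
    prototypes: Dict[str, np.ndarray]            # type -> D-vector
    sigma: Dict[str, float]                      # within-type spread
    marker_prototypes: Dict[str, np.ndarray]     # disease class -> D-vector
    marker_shifts: Dict[str, np.ndarray]         # disease class -> shift applied


@dataclass
class SyntheticCohortConfig:
    D: int = 64
    vocabulary: Sequence[str] = DEFAULT_SYNTHETIC_VOCAB
    class_compositions: Dict[str, Dict[str, float]] = field(default_factory=dict)
    marker_specs: Dict[str, MarkerSpec] = field(default_factory=dict)
    composition_concentration: float = 150.0   # Dirichlet total mass per slide
    n_cells_mean: int = 2000
    n_patients: Dict[str, int] = field(default_factory=dict)
    slides_per_patient: int = 1
    noise_sigma: float = 0.25
    prototype_min_distance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.vocabulary = tuple(self.vocabulary)
        if len(self.vocabulary) < 2:
            raise ValueError("vocabulary needs at least two cell types")
        if self.D < 2:
            raise ValueError("embedding dimension must be >= 2")
        for cls, comp in self.class_compositions.items():
            total = math.fsum(comp.values())
            if total <= 0:
                raise ValueError(f"class {cls!r}: composition weights must be positive")
            self.class_compositions[cls] = {t: w / total for t, w in comp.items()}

    @property
    def classes(self) -> Tuple[str, ...]:
        return tuple(self.class_compositions)


def default_cohort_config(seed: int = 0) -> SyntheticCohortConfig:
    """A miniature four-class cohort (AL/MDS/HCL/NL = 60/30/20/40 slides).

    AL adds morphologically shifted blasts; MDS morphs a fraction of
    neutrophils in place (dysplasia); HCL adds shifted lymphocytes that the
    encoder mislabels as monocytes (hairy cells); NL carries no marker.
    """
    normal = dict(_NORMAL_DIFFERENTIAL)
    return SyntheticCohortConfig(
        class_compositions={
            "AL": normal, "MDS": normal, "HCL": normal, "NL": normal,
        },
        marker_specs={
            "AL": MarkerSpec("blast", (0.10, 0.60), shift_scale=1.0, mode="additive"),
            "MDS": MarkerSpec("segmented_neutrophil", (0.20, 0.50), shift_scale=0.8,
                              mode="in_type"),
            "HCL": MarkerSpec("lymphocyte", (0.10, 0.40), shift_scale=1.2,
                              mode="additive", mislabel_as="monocyte"),
        },
        n_patients={"AL": 60, "MDS": 30, "HCL": 20, "NL": 40},
        seed=seed,
    )


def two_class_config(signal: str, n_patients: Tuple[int, int] = (40, 40),
                     n_cells_mean: int = 2000, D: int = 64,
                     seed: int = 0) -> SyntheticCohortConfig:
    """Disease-vs-normal cohort with a chosen signal type.

    ``signal``: ``'both'`` (extra, morphologically shifted blasts),
    ``'composition'`` (extra blasts, no morphology shift), or
    ``'morphology'`` (unchanged differential; a fraction of lymphocytes are
    morphologically shifted in place).
    """
    if signal == "both":
        spec = MarkerSpec("blast", (0.10, 0.50), shift_scale=1.0, mode="additive")
    elif signal == "composition":
        spec = MarkerSpec("blast", (0.10, 0.50), shift_scale=0.0, mode="additive")
    elif signal == "morphology":
        # rare in-place sub-population: the differential stays uninformative
        spec = MarkerSpec("lymphocyte", (0.05, 0.15), shift_scale=1.0, mode="in_type")
    else:
        raise ValueError(f"unknown signal type {signal!r}")
    normal = dict(_NORMAL_DIFFERENTIAL)
    return SyntheticCohortConfig(
        class_compositions={"NL": normal, "AL": normal},
        marker_specs={"AL": spec},
        n_patients={"NL": n_patients[1], "AL": n_patients[0]},
        n_cells_mean=n_cells_mean,
        D=D,
        seed=seed,
    )


def make_prototypes(config: SyntheticCohortConfig) -> CellPrototypeSet:
    """Seeded unit-scale prototypes with a guaranteed minimum pairwise distance.

    Disease marker prototypes are the source type's prototype plus a fixed
    random shift of norm ``shift_scale``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    protos: Dict[str, np.ndarray] = {}
    for t in config.vocabulary:
        for _ in range(1000):
            v = rng.normal(size=config.D)
            v /= np.linalg.norm(v)
            if all(np.linalg.norm(v - u) >= config.prototype_min_distance
                   for u in protos.values()):
                protos[t] = v
                break
        else:
            raise RuntimeError("could not place prototypes at the requested min distance")
    marker_protos, marker_shifts = {}, {}
    for cls, spec in config.marker_specs.items():
        if spec.source_type not in protos:
            raise ValueError(f"marker source type {spec.source_type!r} not in vocabulary")
        shift = rng.normal(size=config.D)
        shift *= spec.shift_scale / np.linalg.norm(shift) if spec.shift_scale > 0 else 0.0
        marker_shifts[cls] = shift
        marker_protos[cls] = protos[spec.source_type] + shift
    sigma = {t: config.noise_sigma for t in config.vocabulary}
    return CellPrototypeSet(prototypes=protos, sigma=sigma,
                            marker_prototypes=marker_protos, marker_shifts=marker_shifts)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sample_bag(class_label: str, prototypes: CellPrototypeSet,
               config: SyntheticCohortConfig, seed, slide_id: str = "synthetic",
               patient_id: str = "synthetic-patient") -> SlideRecord:
    """Draw one slide: composition from the class Dirichlet, cells as
    prototype + isotropic noise, marker cells per the class MarkerSpec."""
    if class_label not in config.class_compositions:
        raise ValueError(f"class {class_label!r} not configured")
    rng = np.random.default_rng(seed)
    comp = config.class_compositions[class_label]
    vocab = config.vocabulary
    alphas = np.array([comp.get(t, 0.0) * config.composition_concentration + 1e-6
                       for t in vocab])
    fractions = rng.dirichlet(alphas)
    n_cells = max(2, int(rng.poisson(config.n_cells_mean)))

    spec = config.marker_specs.get(class_label)
    marker_fraction = 0.0
    if spec is not None:
        lo, hi = spec.fraction_range
        marker_fraction = float(rng.uniform(lo, hi)) if hi > lo else lo
    n_marker = _round_half_up(marker_fraction * n_cells)

    types: List[str] = []
    refs: List[str] = []
    rows: List[np.ndarray] = []

    def emit(proto: np.ndarray, sigma: float, label: str, ref: str):
        rows.append(proto + rng.normal(scale=sigma, size=config.D))
        types.append(label)
        refs.append(ref)

    if spec is not None and spec.mode == "in_type":
        counts = rng.multinomial(n_cells, fractions)
        for t, c in zip(vocab, counts):
            if spec.source_type == t and c > 0:
                n_morph = min(c, _round_half_up(marker_fraction * n_cells))
                n_morph = min(n_morph, c)
                for _ in range(n_morph):
                    emit(prototypes.marker_prototypes[class_label],
                         prototypes.sigma[t], spec.mislabel_as or t, MARKER_REF)
                c -= n_morph
            for _ in range(c):
                emit(prototypes.prototypes[t], prototypes.sigma[t], t, BACKGROUND_REF)
        blast_fraction = refs.count(MARKER_REF) / n_cells
    else:
        n_bg = n_cells - n_marker
        counts = rng.multinomial(n_bg, fractions) if n_bg > 0 else np.zeros(len(vocab), int)
        for t, c in zip(vocab, counts):
            for _ in range(c):
                emit(prototypes.prototypes[t], prototypes.sigma[t], t, BACKGROUND_REF)
        if spec is not None:
            label = spec.mislabel_as or spec.source_type
            for _ in range(n_marker):
                emit(prototypes.marker_prototypes[class_label],
                     prototypes.sigma[spec.source_type], label, MARKER_REF)
        blast_fraction = n_marker / n_cells if spec is not None else 0.0

    perm = rng.permutation(len(rows))
    bag = CellBag(slide_id=slide_id,
                  embeddings=np.asarray(rows)[perm],
                  cell_types=[types[i] for i in perm],
                  cell_refs=[refs[i] for i in perm])
    return SlideRecord(bag=bag, patient_id=patient_id, label=class_label,
                       blast_fraction=blast_fraction,
                       classes=tuple(config.class_compositions))


def generate_cohort(config: SyntheticCohortConfig) -> List[SlideRecord]:
    """Generate the configured cohort; deterministic in the config seed."""
    prototypes = make_prototypes(config)
    records = []
    for ci, cls in enumerate(config.classes):
        n_pat = config.n_patients.get(cls, 0)
        for pi in range(n_pat):
            pid = f"P-{cls}-{pi:04d}"
            for si in range(config.slides_per_patient):
                sid = f"S-{cls}-{pi:04d}-{si}"
                seed = np.random.SeedSequence([config.seed, 7, ci, pi, si])
                records.append(sample_bag(cls, prototypes, config, seed,
                                          slide_id=sid, patient_id=pid))
    return records


def marker_flags(bag: CellBag) -> np.ndarray:
    """Ground-truth planted-marker flags recorded in cell_refs at generation."""
    if bag.cell_refs is None:
        raise ValueError(f"bag {bag.slide_id!r} carries no provenance refs")
    return np.array([r == MARKER_REF for r in bag.cell_refs], dtype=bool)


def extract_pools(records: Sequence[SlideRecord], normal_label: str = "NL",
                  disease_label: str = "AL") -> Tuple[np.ndarray, np.ndarray]:
    """Pool non-marker cells from normal slides and marker cells from disease
    slides — the ingredients of synthetic-patient mixing."""
    normal_cells, blast_cells = [], []
    for rec in records:
        flags = marker_flags(rec.bag)
        if rec.label == normal_label:
            normal_cells.append(rec.bag.embeddings[~flags])
        elif rec.label == disease_label:
            blast_cells.append(rec.bag.embeddings[flags])
    if not normal_cells or not blast_cells:
        raise ValueError("need at least one normal and one disease slide")
    return np.vstack(normal_cells), np.vstack(blast_cells)


def mix_synthetic_patient(normal_pool: np.ndarray, blast_pool: np.ndarray,
                          blast_fraction: float, n_cells: int, seed,
                          slide_id: str = "synthetic-mix") -> CellBag:
    """Mix round(f*n) blast cells with (n - round(f*n)) normal cells,
    both sampled without replacement, then shuffle."""
    if not 0.0 <= blast_fraction <= 1.0:
        raise ValueError("blast_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    n_blast = _round_half_up(blast_fraction * n_cells)
    n_normal = n_cells - n_blast
    if n_blast > len(blast_pool):
        raise ValueError(f"blast pool exhausted: need {n_blast}, have {len(blast_pool)}")
    if n_normal > len(normal_pool):
        raise ValueError(f"normal pool exhausted: need {n_normal}, have {len(normal_pool)}")
    parts = []
    if n_normal:
        parts.append(normal_pool[rng.choice(len(normal_pool), n_normal, replace=False)])
    if n_blast:
        parts.append(blast_pool[rng.choice(len(blast_pool), n_blast, replace=False)])
    cells = np.vstack(parts)[rng.permutation(n_cells)]
    refs = None  # provenance deliberately withheld: mixing emulates an unlabeled slide
    bag = CellBag(slide_id=slide_id, embeddings=cells, cell_refs=refs)
    return bag, n_blast / n_cells


DEFAULT_LOD_FRACTIONS = (0.0, 0.01, 0.02, 0.05, 0.10, 0.15, 0.20)


def lod_experiment(model, normal_pool: np.ndarray, blast_pool: np.ndarray,
                   fractions: Sequence[float] = DEFAULT_LOD_FRACTIONS,
                   reps: int = 30, cutoff: float = 0.5, n_cells: int = 500,
                   seed: int = 0, disease_index: int = 1) -> pd.DataFrame:
    """Limit-of-detection curve: mean predicted disease probability and call
    rate (P >= cutoff) over synthetic patients at each blast fraction."""
    from .training import _proba_fn  # late import; training already imports models

    if reps < 1:
        raise ValueError("reps must be >= 1")
    fn = _proba_fn(model)
    rows = []
    ss = np.random.SeedSequence([seed, 13])
    for fi, f in enumerate(fractions):
        probs = []
        for rep in range(reps):
            bag, actual = mix_synthetic_patient(
                normal_pool, blast_pool, f, n_cells,
                seed=np.random.SeedSequence([seed, 13, fi, rep]),
                slide_id=f"mix-f{f:g}-r{rep}")
            probs.append(float(fn(bag)[disease_index]))
        probs = np.asarray(probs)
        rows.append({"fraction": f, "n": reps,
                     "mean_probability": probs.mean(),
                     "call_rate": float((probs >= cutoff).mean()),
                     "seed": seed})
    return pd.DataFrame(rows)
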