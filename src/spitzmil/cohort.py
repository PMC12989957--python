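"""Synthetic cohorts of Spitz tumors and conventional melanomas.

Real whole-slide images and encoder features for this problem are private,
so this module generates cohorts that emulate the statistical structure the
downstream analysis assumes: label prevalences matching the study dataset
(393 Spitz / 379 conventional melanomas; grouped aberration prevalences of
roughly 15/27/28/30% for ALK/ROS1/NTRK/other and grouped diagnostic-category
prevalences of roughly 53/34/13%), class-conditional clinical covariates,
variable-size bags of tile feature vectors with a controllable class signal,
and an affine covariate shift between internal and consultation slides.

The feature model is an isotropic Gaussian mixture: a per-bag fraction of
"lesion" tiles is drawn around a class-specific centroid (a combination of
orthonormal direction vectors for the pathway and, for Spitz cases, the
aberration and category), the rest around a shared zero-mean background.
This is a controllable stand-in for real encoder geometry, not a claim
about it.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .tessellation import TissueMask

__all__ = [
    "PATHWAYS",
    "ABERRATIONS",
    "CATEGORIES",
    "LOCATIONS",
    "CohortSpec",
    "LesionRecord",
    "FeatureBag",
    "sample_cohort",
    "sample_feature_bag",
    "make_synthetic_mask",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_bags_h5",
    "read_bags_h5",
]

PATHWAYS = ("spitz", "melanoma")
ABERRATIONS = ("ALK", "ROS1", "NTRK", "other")
CATEGORIES = ("benign", "intermediate", "malignant")
LOCATIONS = ("head_neck", "trunk", "upper_ext", "lower_ext", "hands_feet", "unknown")

# Class-conditional clinical parameters estimated from the study cohort's
# printed summary: age median/IQR, sex and site percentages.
_DEFAULT_CLINICAL = {
    "spitz": {
        "age_mean": 27.0,
        "age_sd": 12.0,
        "age_range": (1.0, 73.0),
        "p_male": 0.300,
        "location_probs": (0.081, 0.186, 0.168, 0.501, 0.059, 0.005),
    },
    "melanoma": {
        "age_mean": 48.0,
        "age_sd": 16.0,
        "age_range": (3.0, 85.0),
        "p_male": 0.417,
        "location_probs": (0.148, 0.406, 0.145, 0.248, 0.034, 0.019),
    },
}


def _normalized(v: Sequence[float], name: str) -> tuple:
    a = np.asarray(v, dtype=float)
    if np.any(a < 0):
        raise ValueError(f"{name} has negative entries")
    s = a.sum()
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {s!r})")
    return tuple(a)


@dataclass(frozen=True)
class CohortSpec:
    """Generator configuration; defaults reproduce the study-cohort mix."""

    n_lesions: int = 772
    pathway_prev: float = 393.0 / 772.0  # P(spitz)
    aberration_prev: tuple = (59 / 393, 107 / 393, 111 / 393, 116 / 393)
    category_prev: tuple = (209 / 393, 132 / 393, 52 / 393)
    clinical_params: dict = field(default_factory=lambda: _DEFAULT_CLINICAL)
    bag_size_range: tuple = (200, 30_000)
    encoder_dim: int = 64
    signal_fraction_range: tuple = (0.1, 0.6)
    class_separation: float = 2.0
    noise_sd: float = 1.0
    shift_params: tuple = (1.1, 0.2)  # consultation features -> scale * x + offset
    lesions_per_patient_prob: tuple = (0.9, 0.1)  # P(1 lesion), P(2 lesions)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if not (0.0 <= self.pathway_prev <= 1.0):
            raise ValueError("pathway_prev must be a probability")
        _normalized(self.aberration_prev, "aberration_prev")
        _normalized(self.category_prev, "category_prev")
        _normalized(self.lesions_per_patient_prob, "lesions_per_patient_prob")
        for pw in PATHWAYS:
            _normalized(self.clinical_params[pw]["location_probs"], f"{pw} location_probs")
        if self.bag_size_range[0] < 1 or self.bag_size_range[1] < self.bag_size_range[0]:
            raise ValueError("bag_size_range must satisfy 1 <= min <= max")
        lo, hi = self.signal_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("signal_fraction_range must lie within [0, 1]")
        if self.encoder_dim <= 0:
            raise ValueError("encoder_dim must be positive")


@dataclass(frozen=True)
class LesionRecord:
    lesion_id: str
    patient_id: str
    pathway: str  # spitz | melanoma
    aberration: str | None  # present iff spitz
    category: str | None  # present iff spitz
    age: float
    sex: str  # male | female
    location: str
    n_tiles: int
    split: str = ""  # dev_fold_1..5 | test, assigned downstream

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway {self.pathway!r}")
        if (self.pathway == "spitz") != (self.aberration is not None):
            raise ValueError("aberration must be present iff pathway is spitz")
        if (self.pathway == "spitz") != (self.category is not None):
            raise ValueError("category must be present iff pathway is spitz")
        if not (0.0 <= self.age <= 110.0):
            raise ValueError("age outside [0, 110]")
        if self.n_tiles < 1:
            raise ValueError("n_tiles must be >= 1")


@dataclass(frozen=True)
class FeatureBag:
    lesion_id: str
    domain: str  # internal | consultation
    features: np.ndarray  # (n_tiles, encoder_dim)
    tile_coords: np.ndarray  # (n_tiles, 2) int
    signal_mask: np.ndarray | None = None  # ground-truth lesion-tile flag

    def __post_init__(self) -> None:
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain non-finite values")
        if self.tile_coords.shape != (self.features.shape[0], 2):
            raise ValueError("tile_coords must be (n_tiles, 2)")
        if self.signal_mask is not None and self.signal_mask.shape[0] != self.features.shape[0]:
            raise ValueError("signal_mask length must equal n_tiles")

    @property
    def n_tiles(self) -> int:
        return self.features.shape[0]


def sample_cohort(spec: CohortSpec) -> list[LesionRecord]:
    """Draw a labelled cohort; deterministic given ``spec.seed``.

    Patients carry 1 or 2 lesions (all lesions of a patient share the
    pathway, so patient-level splitting is well defined); labels and
    clinical covariates are drawn class-conditionally from the spec.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[LesionRecord] = []
    patient_idx = 0
    while len(records) < spec.n_lesions:
        patient_idx += 1
        pid = f"P{patient_idx:05d}"
        n_here = 1 + rng.choice(len(spec.lesions_per_patient_prob), p=spec.lesions_per_patient_prob)
        pathway = "spitz" if rng.random() < spec.pathway_prev else "melanoma"
        for _ in range(n_here):
            if len(records) >= spec.n_lesions:
                break
            lid = f"L{len(records) + 1:05d}"
            if pathway == "spitz":
                aberration = ABERRATIONS[rng.choice(4, p=spec.aberration_prev)]
                category = CATEGORIES[rng.choice(3, p=spec.category_prev)]
            else:
                aberration = None
                category = None
            clin = spec.clinical_params[pathway]
            lo, hi = clin["age_range"]
            a = (lo - clin["age_mean"]) / clin["age_sd"]
            b = (hi - clin["age_mean"]) / clin["age_sd"]
            # Truncated-normal age via inverse transform.
            fa, fb = ndtr(a), ndtr(b)
            age = float(clin["age_mean"] + clin["age_sd"] * ndtri(fa + rng.random() * (fb - fa)))
            age = round(float(np.clip(age, lo, hi)), 2)
            sex = "male" if rng.random() < clin["p_male"] else "female"
            location = LOCATIONS[rng.choice(6, p=np.asarray(clin["location_probs"]) / np.sum(clin["location_probs"]))]
            log_lo, log_hi = math.log(spec.bag_size_range[0]), math.log(spec.bag_size_range[1])
            n_tiles = int(round(math.exp(rng.uniform(log_lo, log_hi))))
            n_tiles = int(np.clip(n_tiles, spec.bag_size_range[0], spec.bag_size_range[1]))
            records.append(
                LesionRecord(
                    lesion_id=lid,
                    patient_id=pid,
                    pathway=pathway,
                    aberration=aberration,
                    category=category,
                    age=age,
                    sex=sex,
                    location=location,
                    n_tiles=n_tiles,
                )
            )
    return records


def _class_directions(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Orthonormal unit vectors for pathway/aberration/category components.

    Derived from the spec seed only, so all bags of a cohort share the same
    geometry. Requires encoder_dim >= 9.
    """
    if spec.encoder_dim < 9:
        raise ValueError("encoder_dim must be >= 9 to fit the class directions")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xD1]))
    q, _ = np.linalg.qr(rng.standard_normal((spec.encoder_dim, 9)))
    keys = (
        ["path_spitz", "path_melanoma"]
        + [f"ab_{a}" for a in ABERRATIONS]
        + [f"cat_{c}" for c in CATEGORIES]
    )
    return {k: q[:, i] for i, k in enumerate(keys)}


def _centroid(record: LesionRecord, spec: CohortSpec, dirs: dict[str, np.ndarray]) -> np.ndarray:
    if record.pathway == "spitz":
        u = (
            dirs["path_spitz"]
            + 0.5 * dirs[f"ab_{record.aberration}"]
            + 0.5 * dirs[f"cat_{record.category}"]
        )
    else:
        u = dirs["path_melanoma"]
    return spec.class_separation * u


def sample_feature_bag(
    record: LesionRecord,
    spec: CohortSpec,
    domain: str = "internal",
    seed: int | None = None,
) -> FeatureBag:
    """Draw one lesion's bag of tile feature vectors.

    A per-bag signal fraction of tiles is drawn around the class centroid,
    the rest around the zero-mean background; signal tiles are placed at
    random positions so tile order carries no label information. The
    consultation domain applies the affine ``shift_params`` to every vector.
    """
    if domain not in ("internal", "consultation"):
        raise ValueError(f"unknown domain {domain!r}")
    if spec.encoder_dim <= 0:
        raise ValueError("encoder_dim must be positive")
    lid_key = zlib.crc32(record.lesion_id.encode()) & 0x7FFFFFFF  # stable across runs
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed if seed is None else seed, lid_key])
    )
    dirs = _class_directions(spec)
    n = record.n_tiles
    sf = rng.uniform(*spec.signal_fraction_range)
    n_signal = int(round(sf * n))
    centroid = _centroid(record, spec, dirs)

    features = rng.standard_normal((n, spec.encoder_dim)) * spec.noise_sd
    signal_idx = rng.choice(n, size=n_signal, replace=False)
    features[signal_idx] += centroid
    mask = np.zeros(n, dtype=bool)
    mask[signal_idx] = True

    if domain == "consultation":
        scale, offset = spec.shift_params
        features = features * scale + offset

    side = int(math.ceil(math.sqrt(n)))
    flat = np.arange(n)
    coords = np.stack([flat % side, flat // side], axis=1).astype(np.int32)

    return FeatureBag(
        lesion_id=record.lesion_id,
        domain=domain,
        features=features.astype(np.float32),
        tile_coords=coords,
        signal_mask=mask,
    )


def make_synthetic_mask(
    width_px: int,
    height_px: int,
    n_blobs: int,
    pen_strokes: int,
    seed: int | None = None,
    blob_radius_range: tuple = (0.05, 0.25),
) -> TissueMask:
    """Random tissue/pen mask fixture: elliptical blobs plus line strokes.

    ``blob_radius_range`` is in fractions of min(width, height); pass a
    large value (e.g. ``(2.0, 2.0)``) to guarantee a blob covering the
    whole frame.
    """
    from skimage.draw import ellipse, line

    if width_px < 1 or height_px < 1:
        raise ValueError("mask dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    tissue = np.zeros((height_px, width_px), dtype=np.uint8)
    pen = np.zeros_like(tissue)
    base = min(width_px, height_px)
    for _ in range(n_blobs):
        r, c = rng.uniform(0, height_px), rng.uniform(0, width_px)
        r_rad = rng.uniform(*blob_radius_range) * base
        c_rad = rng.uniform(*blob_radius_range) * base
        rr, cc = ellipse(r, c, max(r_rad, 1.0), max(c_rad, 1.0),
                         shape=tissue.shape, rotation=rng.uniform(0, np.pi))
        tissue[rr, cc] = 1
    for _ in range(pen_strokes):
        r0, c0 = rng.integers(height_px), rng.integers(width_px)
        r1, c1 = rng.integers(height_px), rng.integers(width_px)
        rr, cc = line(r0, c0, r1, c1)
        pen[rr, cc] = 1
    return TissueMask(tissue=tissue, pen=pen)


# ---------------------------------------------------------------------------
# I/O: cohort table as CSV, feature bags as HDF5.

_CSV_COLUMNS = [
    "lesion_id", "patient_id", "pathway", "aberration", "category",
    "age", "sex", "location", "n_tiles", "split",
]


def cohort_to_frame(records: Sequence[LesionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "lesion_id": r.lesion_id,
                "patient_id": r.patient_id,
                "pathway": r.pathway,
                "aberration": r.aberration if r.aberration is not None else "",
                "category": r.category if r.category is not None else "",
                "age": r.age,
                "sex": r.sex,
                "location": r.location,
                "n_tiles": r.n_tiles,
                "split": r.split,
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_cohort(frame: pd.DataFrame) -> list[LesionRecord]:
    records = []
    for _, row in frame.iterrows():
        records.append(
            LesionRecord(
                lesion_id=str(row["lesion_id"]),
                patient_id=str(row["patient_id"]),
                pathway=str(row["pathway"]),
                aberration=str(row["aberration"]) if str(row.get("aberration", "")) not in ("", "nan") else None,
                category=str(row["category"]) if str(row.get("category", "")) not in ("", "nan") else None,
                age=float(row["age"]),
                sex=str(row["sex"]),
                location=str(row["location"]),
                n_tiles=int(row["n_tiles"]),
                split=str(row["split"]) if str(row.get("split", "")) not in ("nan",) else "",
            )
        )
    return records


def write_cohort_csv(records: Sequence[LesionRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[LesionRecord]:
    return frame_to_cohort(pd.read_csv(path, keep_default_na=False))


def write_bags_h5(bags: Sequence[FeatureBag], path) -> None:
    """One HDF5 group per lesion: datasets features/coords (+ signal_mask)."""
    with h5py.File(path, "w") as f:
        for bag in bags:
            g = f.create_group(bag.lesion_id)
            g.create_dataset("features", data=bag.features.astype(np.float32))
            g.create_dataset("coords", data=bag.tile_coords.astype(np.int32))
            if bag.signal_mask is not None:
                g.create_dataset("signal_mask", data=bag.signal_mask)
            g.attrs["domain"] = bag.domain
            g.attrs["n_tiles"] = bag.n_tiles


def read_bags_h5(path) -> dict[str, FeatureBag]:
    bags = {}
    with h5py.File(path, "r") as f:
        for lid in f:
            g = f[lid]
            bags[lid] = FeatureBag(
                lesion_id=lid,
                domain=str(g.attrs["domain"]),
                features=np.asarray(g["features"]),
                tile_coords=np.asarray(g["coords"]),
                signal_mask=np.asarray(g["signal_mask"]) if "signal_mask" in g else None,
            )
    return bags
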