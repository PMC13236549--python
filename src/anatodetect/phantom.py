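"""Synthetic co-registered PET/CT phantoms with organ maps and lesion truth.

The generator emulates the statistical structure a PET/CT lesion detector has
to cope with: a body of soft tissue on CT, organs with distinct CT intensity,
physiologically hot organs on PET (brain, heart, liver, bladder analogues)
that act as false-positive bait, and hyperintense lesions of varying size and
multiplicity.  Geometry is shared exactly across modalities, as hybrid
acquisition guarantees for real scanners.

Coordinates are (z, y, x), 0-based; boxes are half-open voxel boxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .boxes import LesionBox3D, boxes_from_mask

__all__ = [
    "ImageVolume", "OrganLabelMap", "OrganRecipe", "PhantomSpec", "CaseRecord",
    "LesionPlacementError", "generate_phantom", "boxes_from_mask",
    "read_nifti", "write_nifti", "split_cohort",
    "default_spec", "easy_spec", "decoy_spec",
    "save_case", "load_case", "generate_cohort", "write_manifest",
]

MAX_ORGAN_LABELS = 104  # ceiling of distinct anatomical labels supported


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageVolume:
    """A 3D scalar volume with voxel spacing (mm) and physical origin."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: str = "zyx"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if self.axes != "zyx":
            raise ValueError("axis order is fixed to (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_geometry(self, other: "ImageVolume") -> bool:
        return (self.shape == other.shape and self.spacing == other.spacing
                and self.origin == other.origin)


@dataclass
class OrganLabelMap:
    """Integer organ labels (0 = background) with name and PET-uptake tables."""

    labels: np.ndarray
    label_table: dict[int, str]
    uptake_class: dict[int, str]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3D")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        unknown = present - set(self.label_table)
        if unknown:
            raise ValueError(f"labels missing from label_table: {sorted(unknown)}")
        if len(present) > MAX_ORGAN_LABELS:
            raise ValueError(f"more than {MAX_ORGAN_LABELS} distinct organ labels")
        bad = {k: v for k, v in self.uptake_class.items() if v not in ("low", "high")}
        if bad:
            raise ValueError(f"uptake_class values must be 'low' or 'high': {bad}")

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.labels, self.spacing, self.origin)


@dataclass(frozen=True)
class OrganRecipe:
    """One organ: an ellipsoid with CT/PET intensity ranges.

    ``center`` and ``radii`` are fractions of the volume shape (per axis for
    radii; a scalar radius means a sphere scaled by the smallest half-extent).
    """

    name: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    ct_range: tuple[float, float]
    uptake_range: tuple[float, float]
    uptake_class: str = "low"


@dataclass(frozen=True)
class PhantomSpec:
    """Full generative recipe for one synthetic case."""

    shape: tuple[int, int, int] = (64, 64, 64)
    organ_recipes: tuple[OrganRecipe, ...] = ()
    lesion_count_law: tuple = ("uniform_int", 1, 4)  # or ("fixed", n), ("poisson", lam)
    lesion_radius_range: tuple[float, float] = (3.0, 6.0)
    lesion_uptake_range: tuple[float, float] = (6.0, 10.0)
    lesion_ct_offset: float = 15.0
    noise_sd_pet: float = 0.15
    noise_sd_ct: float = 20.0
    smoothing_sigma_pet: float = 1.0
    smoothing_sigma_ct: float = 0.5
    decoy_organs: bool = True
    body_axes_frac: tuple[float, float, float] = (0.88, 0.72, 0.72)
    body_ct: float = 40.0
    body_uptake: float = 1.0
    background_ct: float = -1000.0
    background_uptake: float = 0.02
    max_placement_tries: int = 200

    def __post_init__(self):
        if self.lesion_uptake_range[0] <= self.body_uptake:
            raise ValueError(
                "lesions must be PET-hyperintense: lesion_uptake_range minimum "
                f"({self.lesion_uptake_range[0]}) must exceed the body background "
                f"uptake ({self.body_uptake})")


@dataclass
class CaseRecord:
    """One phantom case: aligned volumes, organ map, lesion truth, metadata."""

    case_id: str
    patient_id: str
    ct: ImageVolume
    pet: ImageVolume
    organs: OrganLabelMap
    lesion_mask: np.ndarray
    gt_boxes: list[LesionBox3D]
    group: str = ""

    def __post_init__(self):
        if not self.ct.same_geometry(self.pet):
            raise ValueError("PET and CT must share shape, spacing and origin")
        if self.organs.labels.shape != self.ct.shape:
            raise ValueError("organ map must share the case geometry")
        if self.lesion_mask.shape != self.ct.shape:
            raise ValueError("lesion mask must share the case geometry")


class LesionPlacementError(RuntimeError):
    """Raised when lesions cannot be placed after bounded retries."""


# ---------------------------------------------------------------------------
# built-in anatomical recipes
# ---------------------------------------------------------------------------

_ORGANS = (
    OrganRecipe("brain", (0.14, 0.50, 0.50), (0.10, 0.10, 0.10), (30, 40), (5.0, 7.0), "high"),
    OrganRecipe("heart", (0.34, 0.46, 0.42), (0.08, 0.08, 0.08), (40, 50), (3.5, 5.5), "high"),
    OrganRecipe("lung_right", (0.32, 0.45, 0.28), (0.14, 0.10, 0.10), (-750, -650), (0.2, 0.4), "low"),
    OrganRecipe("lung_left", (0.32, 0.45, 0.72), (0.14, 0.10, 0.10), (-750, -650), (0.2, 0.4), "low"),
    OrganRecipe("liver", (0.52, 0.55, 0.38), (0.11, 0.13, 0.15), (50, 70), (2.0, 3.0), "high"),
    OrganRecipe("bladder", (0.82, 0.55, 0.50), (0.07, 0.07, 0.07), (10, 25), (6.0, 9.0), "high"),
    OrganRecipe("spine", (0.50, 0.72, 0.50), (0.40, 0.045, 0.045), (300, 500), (0.4, 0.7), "low"),
)


def _radius_range(base: tuple[float, float], shape, ref: int) -> tuple[float, float]:
    # lesion radii scale with the volume so presets stay feasible at any size
    s = min(shape) / ref
    return (max(base[0] * s, 2.0), max(base[1] * s, 2.5))


def default_spec(shape=(64, 64, 64)) -> PhantomSpec:
    """Moderate-difficulty phantom with hot decoy organs."""
    return PhantomSpec(shape=tuple(shape), organ_recipes=_ORGANS,
                       lesion_radius_range=_radius_range((3.0, 6.0), shape, 64))


def easy_spec(shape=(48, 48, 48)) -> PhantomSpec:
    """Large, high-contrast lesions without PET decoys (learning-check regime)."""
    return PhantomSpec(
        shape=tuple(shape), organ_recipes=_ORGANS,
        lesion_count_law=("uniform_int", 1, 2),
        lesion_radius_range=_radius_range((5.0, 7.0), shape, 48),
        lesion_uptake_range=(9.0, 13.0),
        noise_sd_pet=0.10, noise_sd_ct=15.0, smoothing_sigma_pet=0.8,
        decoy_organs=False)


def decoy_spec(shape=(48, 48, 48)) -> PhantomSpec:
    """Lesions whose uptake overlaps the hot-organ range (anatomy-prior regime)."""
    return PhantomSpec(
        shape=tuple(shape), organ_recipes=_ORGANS,
        lesion_count_law=("uniform_int", 1, 2),
        lesion_radius_range=_radius_range((4.0, 6.0), shape, 48),
        lesion_uptake_range=(5.0, 9.0),
        lesion_ct_offset=0.0,  # lymphoma is CT-subtle on low-dose ACCT
        noise_sd_pet=0.12, decoy_organs=True)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / max(r, 1e-9)) ** 2
    return acc <= 1.0


def _draw_lesion_count(law: tuple, rng: np.random.Generator) -> int:
    kind = law[0]
    if kind == "fixed":
        return int(law[1])
    if kind == "uniform_int":
        return int(rng.integers(law[1], law[2] + 1))
    if kind == "poisson":
        return int(rng.poisson(law[1]))
    raise ValueError(f"unknown lesion_count_law {law!r}")


def generate_phantom(spec: PhantomSpec, seed: int, case_id: str | None = None,
                     patient_id: str | None = None, group: str = "") -> CaseRecord:
    """Generate one case deterministically from (spec, seed).

    Lesions are placed fully inside the body, pairwise non-overlapping, and
    clear of every hot (decoy) organ, so decoy uptake can never be explained
    away as lesion signal.  Raises :class:`LesionPlacementError` when the
    requested lesion load does not fit after bounded retries.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(spec.shape)
    ct = np.full(shape, spec.background_ct, dtype=np.float32)
    pet = np.full(shape, spec.background_uptake, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int16)

    center = np.array(shape) / 2.0
    body_radii = np.array(spec.body_axes_frac) * np.array(shape) / 2.0
    body = _ellipsoid_mask(shape, center, body_radii)
    ct[body] = spec.body_ct
    pet[body] = spec.body_uptake

    label_table: dict[int, str] = {}
    uptake_class: dict[int, str] = {}
    organ_geoms: list[tuple[OrganRecipe, np.ndarray, float]] = []
    for i, organ in enumerate(spec.organ_recipes, start=1):
        oc = np.array(organ.center) * np.array(shape)
        oc = oc + rng.normal(0.0, 0.01 * min(shape), size=3)  # anatomical jitter
        orad = np.array(organ.radii) * np.array(shape)
        mask = _ellipsoid_mask(shape, oc, orad) & body
        labels[mask] = i
        label_table[i] = organ.name
        uptake_class[i] = organ.uptake_class
        ct[mask] = rng.uniform(*organ.ct_range)
        hot = organ.uptake_class == "high"
        if hot and not spec.decoy_organs:
            pet[mask] = spec.body_uptake
        else:
            pet[mask] = rng.uniform(*organ.uptake_range)
        if hot and spec.decoy_organs:
            organ_geoms.append((organ, oc, float(orad.max())))

    # -- lesion placement ---------------------------------------------------
    body_dt = ndimage.distance_transform_edt(body)
    n_lesions = _draw_lesion_count(spec.lesion_count_law, rng)
    placed: list[tuple[np.ndarray, float]] = []
    lesion_mask = np.zeros(shape, dtype=np.uint8)
    for li in range(n_lesions):
        ok = False
        for _ in range(spec.max_placement_tries):
            r = rng.uniform(*spec.lesion_radius_range)
            # candidate centers satisfying every constraint: sphere inside the
            # body, clear of hot organs (so decoy uptake stays pure and the
            # tight gt box cannot touch an organ core), clear of other lesions
            cand = np.argwhere(body_dt > r + 1).astype(float)
            for _, oc, orad in organ_geoms:
                clearance = max(r + orad + 0.5,
                                np.sqrt(3.0) * r + 0.6 * orad + 0.5)
                cand = cand[np.linalg.norm(cand - oc, axis=1) >= clearance]
            for pc, pr in placed:
                cand = cand[np.linalg.norm(cand - pc, axis=1) >= r + pr + 1]
            if cand.shape[0] == 0:
                continue
            c = cand[int(rng.integers(cand.shape[0]))]
            sphere = _ellipsoid_mask(shape, c, (r, r, r))
            lesion_mask[sphere] = 1
            pet[sphere] = rng.uniform(*spec.lesion_uptake_range)
            ct[sphere] += spec.lesion_ct_offset
            placed.append((c, r))
            ok = True
            break
        if not ok:
            raise LesionPlacementError(
                f"placed {len(placed)} of {n_lesions} lesions after "
                f"{spec.max_placement_tries} tries each; spec is infeasible "
                f"for body volume {int(body.sum())} voxels")

    # -- imaging model: noise then point-spread smoothing --------------------
    if spec.noise_sd_ct > 0:
        ct += rng.normal(0.0, spec.noise_sd_ct, size=shape).astype(np.float32)
    if spec.noise_sd_pet > 0:
        pet += rng.normal(0.0, spec.noise_sd_pet, size=shape).astype(np.float32)
    if spec.smoothing_sigma_ct > 0:
        ct = ndimage.gaussian_filter(ct, spec.smoothing_sigma_ct)
    if spec.smoothing_sigma_pet > 0:
        pet = ndimage.gaussian_filter(pet, spec.smoothing_sigma_pet)
    np.clip(pet, 0.0, None, out=pet)

    spacing = (3.0, 3.0, 3.0)  # PET-like voxel size in mm
    cid = case_id if case_id is not None else f"case_{seed:06d}"
    pid = patient_id if patient_id is not None else f"patient_{seed:06d}"
    return CaseRecord(
        case_id=cid, patient_id=pid,
        ct=ImageVolume(ct.astype(np.float32), spacing),
        pet=ImageVolume(pet.astype(np.float32), spacing),
        organs=OrganLabelMap(labels, label_table, uptake_class, spacing),
        lesion_mask=lesion_mask,
        gt_boxes=boxes_from_mask(lesion_mask),
        group=group,
    )


# ---------------------------------------------------------------------------
# NIfTI and cohort I/O
# ---------------------------------------------------------------------------


def write_nifti(vol: ImageVolume, path) -> None:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.data, affine), str(path))


def read_nifti(path) -> ImageVolume:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    img = nib.load(str(p))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D: {p}")
    affine = img.affine
    spacing = tuple(float(abs(affine[i, i])) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    return ImageVolume(data, spacing, origin)


def split_cohort(patient_ids: list, train_fraction: float, seed: int):
    """Patient-level hold-out split with round-half-up train sizing."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids: {dupes}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(ids)
    n_train = int(np.floor(train_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_set = {ids[i] for i in perm[:n_train]}
    train = [i for i in ids if i in train_set]
    test = [i for i in ids if i not in train_set]
    return train, test


def save_case(case: CaseRecord, out_dir) -> Path:
    """Write one case as {ct, pet, organs, lesions}.nii.gz + a JSON sidecar."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    stem = case.case_id
    write_nifti(case.ct, d / f"{stem}_ct.nii.gz")
    write_nifti(case.pet, d / f"{stem}_pet.nii.gz")
    write_nifti(case.organs.as_volume(), d / f"{stem}_organs.nii.gz")
    write_nifti(ImageVolume(case.lesion_mask.astype(np.uint8), case.ct.spacing,
                            case.ct.origin), d / f"{stem}_lesions.nii.gz")
    sidecar = {
        "case_id": case.case_id,
        "patient_id": case.patient_id,
        "group": case.group,
        "gt_boxes": [{"lo": list(b.lo), "hi": list(b.hi), "label": b.label}
                     for b in case.gt_boxes],
        "label_table": {str(k): v for k, v in case.organs.label_table.items()},
        "uptake_class": {str(k): v for k, v in case.organs.uptake_class.items()},
    }
    (d / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return d


def load_case(case_dir, case_id: str) -> CaseRecord:
    d = Path(case_dir)
    meta = json.loads((d / f"{case_id}.json").read_text())
    ct = read_nifti(d / f"{case_id}_ct.nii.gz")
    pet = read_nifti(d / f"{case_id}_pet.nii.gz")
    organs_vol = read_nifti(d / f"{case_id}_organs.nii.gz")
    lesions = read_nifti(d / f"{case_id}_lesions.nii.gz")
    organs = OrganLabelMap(
        organs_vol.data.astype(np.int16),
        {int(k): v for k, v in meta["label_table"].items()},
        {int(k): v for k, v in meta["uptake_class"].items()},
        organs_vol.spacing, organs_vol.origin)
    boxes = [LesionBox3D(tuple(b["lo"]), tuple(b["hi"]), label=b.get("label", 1))
             for b in meta["gt_boxes"]]
    return CaseRecord(meta["case_id"], meta["patient_id"], ct, pet, organs,
                      lesions.data.astype(np.uint8), boxes, meta.get("group", ""))


def generate_cohort(spec: PhantomSpec, n_cases: int, seed: int,
                    group_of=None) -> list[CaseRecord]:
    """Generate ``n_cases`` phantoms with per-case seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        case_seed = int(rng.integers(0, 2**31 - 1))
        group = group_of(i) if group_of is not None else ""
        cases.append(generate_phantom(
            spec, case_seed, case_id=f"case_{i:04d}",
            patient_id=f"patient_{i:04d}", group=group))
    return cases


def write_manifest(cases: list[CaseRecord], train_ids: list, path) -> pd.DataFrame:
    """Cohort manifest CSV: case_id, patient_id, group, split."""
    rows = [{"case_id": c.case_id, "patient_id": c.patient_id, "group": c.group,
             "split": "train" if c.patient_id in set(train_ids) else "test"}
            for c in cases]
    df = pd.DataFrame(rows, columns=["case_id", "patient_id", "group", "split"])
    df.to_csv(path, index=False)
    return df
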