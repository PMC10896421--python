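"""Synthetic phantoms, cohorts and serum tables with known ground truth.

The study's raw two-channel cryo-imaging stacks are not public, so this
module provides a forward model of the acquisition that every downstream
stage can be validated against:

    raw(s, i, j) = dark + illumination(i, j) * field(s, i, j) + noise

per slice ``s`` and channel, clipped to nonnegative counts.  The tissue
is an ellipsoid-like stack of per-slice ellipses whose axes shrink
toward the end slices; the illumination pattern is a centered Gaussian
vignette normalized to unit mean; dark current is a constant offset with
additive Gaussian read noise (Poisson shot noise optional).

Cohorts emulate the study design: two genotypes (WT/KO) by two sexes,
per-animal true redox ratios drawn lognormally around the genotype mean,
with the genotype effect expressed through the NADH channel by default
(FAD shared across genotypes).  Each animal's realized voxel field is
normalized so its tissue-mean RR equals its drawn truth exactly, making
the manifest's ``true_mean_rr`` an exact oracle for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationFrames, ImageStack

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "CohortSpec",
    "SerumSpec",
    "SyntheticAnimal",
    "generate_phantom_stack",
    "generate_cohort",
    "generate_serum_table",
    "liver_cohort_spec",
    "kidney_cohort_spec",
    "young_serum_spec",
    "aged_serum_spec",
    "write_cohort",
]

# Printed group-mean redox ratios used as generator defaults.
LIVER_WT_RR = 2.59
LIVER_KO_RR = 1.77
KIDNEY_WT_RR = 0.85
KIDNEY_KO_RR = 0.69


def _lognormal_mean1(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Lognormal multipliers with arithmetic mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else np.float64(1.0)
    s2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=size)


def ellipsoid_mask(shape: tuple[int, int, int], radius_frac: float = 0.38) -> np.ndarray:
    """Per-slice ellipse mask with axes shrinking toward end slices."""
    nz, ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    mask = np.zeros(shape, dtype=bool)
    for k in range(nz):
        z = (k + 0.5) / nz  # relative depth in (0, 1)
        scale = np.sqrt(max(0.0, 1.0 - ((z - 0.5) / 0.5) ** 2))
        a, b = scale * radius_frac * ny, scale * radius_frac * nx
        if a < 1 or b < 1:
            continue  # end slice past the organ
        mask[k] = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    return mask


def gaussian_vignette(frame_shape: tuple[int, int], strength: float = 1.3) -> np.ndarray:
    """Centered Gaussian illumination field, peak/edge ratio ``strength``, mean 1."""
    if strength < 1:
        raise ValueError("vignette strength must be >= 1")
    ny, nx = frame_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = (((yy - (ny - 1) / 2) / (ny / 2)) ** 2
          + ((xx - (nx - 1) / 2) / (nx / 2)) ** 2)
    # exp(-r2 * log(strength)) spans [1/strength, 1] corner-to-center
    illum = np.exp(-r2 * np.log(strength) / 2.0)
    return illum / illum.mean()


@dataclass
class PhantomParams:
    """Forward-model parameters for one two-channel phantom stack.

    Intensity levels are in camera counts; ``rr = nadh_level/fad_level``
    is the phantom's true redox ratio when ``voxel_rr_cv = 0``.  The
    default 40-slice depth keeps simulations fast; full acquisition depth
    (200 slices) is available by overriding ``shape``.
    """

    shape: tuple[int, int, int] = (40, 64, 64)
    nadh_level: float = 2000.0
    fad_level: float = 1000.0
    voxel_rr_cv: float = 0.0       # voxel-level RR heterogeneity within the tissue
    brightness_cv: float = 0.1     # shared spatial texture of both channels
    vignette_strength: float = 1.3
    dark_level: float = 100.0
    noise_sd: float = 5.0
    poisson: bool = False
    radius_frac: float = 0.38
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError("phantom shape must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.nadh_level <= 0 or self.fad_level <= 0:
            raise ValueError("channel levels must be positive")
        if self.dark_level < 0:
            raise ValueError("dark_level must be nonnegative")


@dataclass
class PhantomTruth:
    """Ground-truth fields behind one generated phantom stack."""

    nadh_field: np.ndarray
    fad_field: np.ndarray
    tissue_mask: np.ndarray
    illumination: np.ndarray
    dark_level: float
    noise_sd: float
    rng_seed: int

    @property
    def true_mean_rr(self) -> float:
        m = self.tissue_mask
        return float((self.nadh_field[m] / self.fad_field[m]).mean())


def _make_fields(params: PhantomParams, rng: np.random.Generator):
    """Noise-free NADH/FAD intensity fields, zero outside the tissue mask."""
    mask = ellipsoid_mask(params.shape, params.radius_frac)
    if not mask.any():
        raise ValueError("phantom tissue mask is empty; enlarge shape or radius_frac")
    texture = _lognormal_mean1(rng, params.brightness_cv, size=params.shape)
    ratio = _lognormal_mean1(rng, params.voxel_rr_cv, size=params.shape)
    # normalize realized ratio texture to tissue-mean 1 so the phantom's
    # mean RR equals nadh_level/fad_level exactly
    ratio = ratio / ratio[mask].mean()
    fad = np.where(mask, params.fad_level * texture, 0.0)
    nadh = np.where(mask, params.nadh_level * texture * ratio, 0.0)
    return nadh, fad, mask


def generate_phantom_stack(
    params: PhantomParams,
) -> tuple[ImageStack, ImageStack, CalibrationFrames, PhantomTruth]:
    """Simulate a raw two-channel stack plus its exact calibration frames.

    The returned :class:`CalibrationFrames` hold the very dark and
    illumination fields applied, so dark/flat correction inverts the
    forward model exactly when ``noise_sd = 0``.  Identical parameters
    and seed give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    nadh_field, fad_field, mask = _make_fields(params, rng)
    illum = gaussian_vignette(params.shape[1:], params.vignette_strength)

    stacks = {}
    for channel, fld in (("NADH", nadh_field), ("FAD", fad_field)):
        signal = illum[None, :, :] * fld
        if params.poisson:
            signal = rng.poisson(signal).astype(np.float64)
        raw = params.dark_level + signal
        if params.noise_sd > 0:
            raw = raw + rng.normal(0.0, params.noise_sd, size=raw.shape)
        stacks[channel] = ImageStack(channel=channel, data=np.clip(raw, 0.0, None))

    frame_shape = params.shape[1:]
    frames = CalibrationFrames(
        dark={c: np.full(frame_shape, params.dark_level) for c in ("NADH", "FAD")},
        flat={c: illum.copy() for c in ("NADH", "FAD")},
        gain={c: 1.0 for c in ("NADH", "FAD")},
    )
    truth = PhantomTruth(
        nadh_field=nadh_field, fad_field=fad_field, tissue_mask=mask,
        illumination=illum, dark_level=params.dark_level,
        noise_sd=params.noise_sd, rng_seed=params.seed,
    )
    return stacks["NADH"], stacks["FAD"], frames, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSpec:
    """Design of one synthetic imaging cohort.

    ``n_per_group_by_sex`` maps (genotype, sex) to animal counts;
    ``between_animal_cv`` is the animal-level lognormal CV of the true
    RR around its genotype mean, independent of the voxel-level spread
    ``voxel_rr_cv``.  ``effect_channel`` states which channel carries the
    genotype effect; with ``'nadh'`` the FAD level is shared across
    genotypes and only NADH differs.
    """

    n_per_group_by_sex: dict[tuple[str, str], int]
    tissue: str = "liver"
    wt_rr_mean: float = LIVER_WT_RR
    ko_rr_mean: float = LIVER_KO_RR
    between_animal_cv: float = 0.15
    voxel_rr_cv: float = 0.35
    effect_channel: str = "nadh"
    slices_per_animal: int = 40
    frame_shape: tuple[int, int] = (64, 64)
    slice_thickness_um: float = 100.0
    fad_level: float = 1000.0
    brightness_cv: float = 0.1
    dark_level: float = 100.0
    noise_sd: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_group_by_sex:
            raise ValueError("cohort must contain at least one group")
        if any(n <= 0 for n in self.n_per_group_by_sex.values()):
            raise ValueError("group counts must be positive")
        if self.wt_rr_mean <= 0 or self.ko_rr_mean <= 0:
            raise ValueError("genotype RR means must be positive")
        if self.between_animal_cv < 0:
            raise ValueError("between_animal_cv must be nonnegative")
        if self.effect_channel not in ("nadh", "fad", "both"):
            raise ValueError("effect_channel must be 'nadh', 'fad' or 'both'")
        if self.slices_per_animal <= 0:
            raise ValueError("slices_per_animal must be positive")


def liver_cohort_spec(**overrides) -> CohortSpec:
    """Study liver design: N=8/group (4M, 4F), 100 µm slices, RR 2.59 vs 1.77."""
    base = dict(
        n_per_group_by_sex={("WT", "M"): 4, ("WT", "F"): 4,
                            ("KO", "M"): 4, ("KO", "F"): 4},
        tissue="liver", wt_rr_mean=LIVER_WT_RR, ko_rr_mean=LIVER_KO_RR,
        between_animal_cv=0.15, slice_thickness_um=100.0,
    )
    base.update(overrides)
    return CohortSpec(**base)


def kidney_cohort_spec(**overrides) -> CohortSpec:
    """Study kidney design: N=18/group (11M, 7F), 30 µm slices, RR 0.85 vs 0.69."""
    base = dict(
        n_per_group_by_sex={("WT", "M"): 11, ("WT", "F"): 7,
                            ("KO", "M"): 11, ("KO", "F"): 7},
        tissue="kidney", wt_rr_mean=KIDNEY_WT_RR, ko_rr_mean=KIDNEY_KO_RR,
        between_animal_cv=0.45, slice_thickness_um=30.0,
    )
    base.update(overrides)
    return CohortSpec(**base)


@dataclass
class SyntheticAnimal:
    """One generated animal: raw stacks, calibration frames, and truth."""

    animal_id: str
    genotype: str
    sex: str
    tissue: str
    nadh_raw: ImageStack
    fad_raw: ImageStack
    frames: CalibrationFrames
    truth: PhantomTruth
    true_mean_rr: float


def generate_cohort(spec: CohortSpec) -> tuple[list[SyntheticAnimal], pd.DataFrame]:
    """Generate raw stacks for every animal in the design plus a truth manifest.

    Each animal's true RR is its genotype mean times a mean-1 lognormal
    multiplier with ``between_animal_cv``; the realized voxel field is
    normalized so the tissue-mean RR equals this truth exactly.  The
    manifest has one row per animal (animal_id, genotype, sex, tissue,
    true_mean_rr).
    """
    seeds = np.random.SeedSequence(spec.rng_seed).spawn(
        sum(spec.n_per_group_by_sex.values())
    )
    draw_rng = np.random.default_rng(np.random.SeedSequence((spec.rng_seed, 911)))

    animals: list[SyntheticAnimal] = []
    rows = []
    idx = 0
    for (genotype, sex), n in sorted(spec.n_per_group_by_sex.items()):
        g_mean = spec.wt_rr_mean if genotype == "WT" else spec.ko_rr_mean
        for _ in range(n):
            rr_true = float(g_mean * _lognormal_mean1(draw_rng, spec.between_animal_cv))
            fold = rr_true / spec.wt_rr_mean
            if spec.effect_channel == "nadh":
                nadh_level = spec.fad_level * spec.wt_rr_mean * fold
                fad_level = spec.fad_level
            elif spec.effect_channel == "fad":
                nadh_level = spec.fad_level * spec.wt_rr_mean
                fad_level = spec.fad_level / fold
            else:  # both channels share the effect
                nadh_level = spec.fad_level * spec.wt_rr_mean * np.sqrt(fold)
                fad_level = spec.fad_level / np.sqrt(fold)

            animal_seed = int(seeds[idx].generate_state(1)[0] % (2**31))
            params = PhantomParams(
                shape=(spec.slices_per_animal, *spec.frame_shape),
                nadh_level=nadh_level, fad_level=fad_level,
                voxel_rr_cv=spec.voxel_rr_cv, brightness_cv=spec.brightness_cv,
                dark_level=spec.dark_level, noise_sd=spec.noise_sd,
                seed=animal_seed,
            )
            nadh_raw, fad_raw, frames, truth = generate_phantom_stack(params)
            animal_id = f"{spec.tissue}_{genotype}_{sex}_{idx:03d}"
            for stk in (nadh_raw, fad_raw):
                stk.animal_id = animal_id
                stk.slice_thickness_um = spec.slice_thickness_um
            animals.append(SyntheticAnimal(
                animal_id=animal_id, genotype=genotype, sex=sex,
                tissue=spec.tissue, nadh_raw=nadh_raw, fad_raw=fad_raw,
                frames=frames, truth=truth, true_mean_rr=rr_true,
            ))
            rows.append(dict(animal_id=animal_id, genotype=genotype, sex=sex,
                             tissue=spec.tissue, true_mean_rr=rr_true))
            idx += 1
    return animals, pd.DataFrame(rows)


def draw_true_means(spec: CohortSpec) -> pd.DataFrame:
    """Draw only the per-animal true mean RRs (no images) for design studies.

    Uses the same animal-level sampling scheme as :func:`generate_cohort`.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.rng_seed, 911)))
    rows = []
    idx = 0
    for (genotype, sex), n in sorted(spec.n_per_group_by_sex.items()):
        g_mean = spec.wt_rr_mean if genotype == "WT" else spec.ko_rr_mean
        for _ in range(n):
            rr = float(g_mean * _lognormal_mean1(rng, spec.between_animal_cv))
            rows.append(dict(animal_id=f"a{idx:04d}", genotype=genotype, sex=sex,
                             tissue=spec.tissue, true_mean_rr=rr))
            idx += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serum panels


@dataclass
class SerumSpec:
    """Design of a synthetic clinical-chemistry panel.

    ``analytes`` is a list of (name, wt_mean, units, ko_fold_change, cv);
    KO means equal ``wt_mean * fold`` in expectation, with mean-1
    lognormal animal variation of the given CV.
    """

    analytes: list[tuple[str, float, str, float, float]]
    n_per_group: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        for name, wt_mean, _units, fold, cv in self.analytes:
            if wt_mean <= 0:
                raise ValueError(f"{name}: wt_mean must be positive")
            if fold <= 0:
                raise ValueError(f"{name}: fold change must be positive")
            if cv < 0:
                raise ValueError(f"{name}: cv must be nonnegative")


def young_serum_spec(**overrides) -> SerumSpec:
    """Young-adult panel (9-14 wk): BUN +17.5%, glucose +23.8%, heart +11.5%."""
    base = dict(
        analytes=[
            ("BUN", 22.0, "mg/dL", 1.175, 0.10),
            ("cholesterol", 100.0, "mg/dL", 1.0, 0.10),
            ("glucose", 180.0, "mg/dL", 1.238, 0.10),
            ("insulin", 1.0, "ng/mL", 1.0, 0.15),
            ("creatinine", 0.2, "mg/dL", 1.0, 0.10),
            ("heart_weight", 0.15, "g", 1.115, 0.05),
        ],
        n_per_group=10,
    )
    base.update(overrides)
    return SerumSpec(**base)


def aged_serum_spec(**overrides) -> SerumSpec:
    """Aged panel (18-20 mo): glucose +79.9%, small cholesterol decrease."""
    base = dict(
        analytes=[
            ("cholesterol", 110.0, "mg/dL", 0.93, 0.08),
            ("glucose", 180.0, "mg/dL", 1.799, 0.10),
        ],
        n_per_group=6,
    )
    base.update(overrides)
    return SerumSpec(**base)


def generate_serum_table(spec: SerumSpec) -> pd.DataFrame:
    """One row per animal per analyte: animal_id, genotype, sex, analyte, value."""
    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    for genotype in ("WT", "KO"):
        for i in range(spec.n_per_group):
            animal_id = f"serum_{genotype}_{i:03d}"
            sex = "M" if i % 2 == 0 else "F"
            for name, wt_mean, units, fold, cv in spec.analytes:
                mean = wt_mean * (fold if genotype == "KO" else 1.0)
                value = float(mean * _lognormal_mean1(rng, cv))
                rows.append(dict(animal_id=animal_id, genotype=genotype, sex=sex,
                                 analyte=name, value=value, units=units))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk cohort layout


def write_cohort(animals: list[SyntheticAnimal], manifest: pd.DataFrame,
                 outdir: str | Path, spec: CohortSpec | None = None) -> Path:
    """Write a cohort as TIFF stacks + manifest.csv + truth.json.

    Layout: ``<animal_id>_{nadh,fad}.tif`` (16-bit multi-page),
    ``calibration_{dark,flat}_{nadh,fad}.tif``, ``manifest.csv`` with
    file paths, and a ``truth.json`` sidecar with generator parameters.
    """
    from .io import write_stack, write_frame  # deferred: io imports tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    nadh_paths, fad_paths = [], []
    for a in animals:
        np_path = outdir / f"{a.animal_id}_nadh.tif"
        fp_path = outdir / f"{a.animal_id}_fad.tif"
        write_stack(a.nadh_raw, np_path)
        write_stack(a.fad_raw, fp_path)
        nadh_paths.append(np_path.name)
        fad_paths.append(fp_path.name)
    manifest["nadh_path"] = nadh_paths
    manifest["fad_path"] = fad_paths
    manifest.to_csv(outdir / "manifest.csv", index=False)

    # one set of calibration frames per cohort (shared acquisition session)
    frames = animals[0].frames
    for c in ("NADH", "FAD"):
        write_frame(frames.dark[c], outdir / f"calibration_dark_{c.lower()}.tif")
        write_frame(frames.flat[c], outdir / f"calibration_flat_{c.lower()}.tif")

    sidecar: dict = {"n_animals": len(animals)}
    if spec is not None:
        d = asdict(spec)
        d["n_per_group_by_sex"] = {f"{g}/{s}": n
                                   for (g, s), n in spec.n_per_group_by_sex.items()}
        sidecar["cohort_spec"] = d
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=2))
    return outdir
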