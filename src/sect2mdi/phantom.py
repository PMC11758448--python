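"""Synthetic paired-DECT brain phantoms.

Clinical context: after endovascular thrombectomy, a bright region on
non-contrast CT (a postinterventional cerebral hyperdensity) can be either
extravasated blood (intracranial hemorrhage, ICH) or retained iodinated
contrast (contrast staining, CS).  The two are indistinguishable by
attenuation on single-energy CT (SECT), but dual-energy CT separates them
into a virtual non-contrast image (VNC; blood stays visible) and an iodine
overlay map (IOM; iodine signal only).

This module generates matched (SECT, VNC, IOM) triplets from an explicit
linearized three-material forward model,

    SECT = blur(VNC + k * IOM) + noise,

so that decomposition is a well-posed learning target.  The two lesion
classes draw their added intensity from identical ranges — mean lesion
brightness on SECT carries (almost) no class information, mirroring the
clinical premise — while morphology differs: blood lesions have sharp
margins and correlated internal speckle (clot heterogeneity), iodine
staining has smooth margins and a uniform interior (contrast pooling in
infarcted parenchyma).  A network must therefore exploit texture and edge
profile, not brightness, to route lesion intensity into VNC or IOM.

Intensities live in the normalized [0, 256] range used by the preprocessing
pipeline throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "ICH", "CS", "MIXED", "LesionSpec", "PhantomConfig", "PairedCase",
    "PlacementError", "brain_mask", "sample_lesions", "render_case",
    "simulate_case", "simulate_cohort", "classify_by_decomposition",
    "decomposition_score", "stratified_split", "save_case", "load_case",
    "write_manifest",
]

ICH = "ICH"
CS = "CS"
MIXED = "MIXED"

INTENSITY_RANGE = (0.0, 256.0)


class PlacementError(RuntimeError):
    """Raised when a lesion cannot be placed inside the brain mask."""


@dataclass(frozen=True)
class LesionSpec:
    """One ellipsoidal focal hyperdensity.

    ``blood_intensity`` is added to the VNC image, ``iodine_intensity`` to the
    IOM; the SECT appearance is their mixture via the forward model.
    """

    center: tuple[float, ...]
    radii: tuple[float, ...]
    kind: str
    blood_intensity: float
    iodine_intensity: float

    def __post_init__(self):
        if self.kind not in (ICH, CS, MIXED):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if len(self.center) != len(self.radii):
            raise ValueError("center and radii rank mismatch")
        if self.kind == ICH and not (self.blood_intensity > 0 and self.iodine_intensity == 0):
            raise ValueError("ICH lesions carry blood only")
        if self.kind == CS and not (self.iodine_intensity > 0 and self.blood_intensity == 0):
            raise ValueError("CS lesions carry iodine only")
        if self.kind == MIXED and not (self.blood_intensity > 0 and self.iodine_intensity > 0):
            raise ValueError("MIXED lesions carry both materials")


@dataclass(frozen=True)
class PhantomConfig:
    """Forward-model and cohort parameters (defaults: 2D desk scale).

    ``blood_range`` and ``iodine_range`` deliberately coincide so an intensity
    threshold on SECT cannot separate the classes; ``mixing_coefficient`` is
    the iodine-to-attenuation scale k of the forward model.
    """

    grid_shape: tuple[int, ...] = (64, 64)
    voxel_spacing: tuple[float, ...] = (1.0, 1.0)
    background_mean: float = 60.0
    background_sd: float = 4.0
    lesion_count_range: tuple[int, int] = (1, 3)
    class_prevalence: float = 0.32
    blood_range: tuple[float, float] = (40.0, 90.0)
    iodine_range: tuple[float, float] = (40.0, 90.0)
    mixing_coefficient: float = 1.0
    noise_sd: float = 2.0
    blur_sigma: float = 0.6
    radius_range: tuple[float, float] = (2.5, 6.0)
    ich_edge_sigma: float = 0.5
    cs_edge_sigma: float = 2.5
    ich_texture_sd: float = 0.25
    texture_corr_sigma: float = 1.0
    # iodine staining sits inside the infarcted territory: a smooth
    # hypodense non-enhancing margin surrounds (but does not underlie) each
    # iodine-bearing lesion on VNC; blood lesions lack it
    halo_depth: float = 12.0
    halo_width: float = 4.0
    halo_sigma: float = 1.5
    mixed_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != len(self.voxel_spacing):
            raise ValueError("grid_shape and voxel_spacing rank mismatch")
        if not 0.0 < self.class_prevalence < 1.0:
            raise ValueError("class_prevalence must lie strictly in (0, 1)")
        if self.mixing_coefficient <= 0:
            raise ValueError("mixing coefficient k must be positive")
        for name in ("lesion_count_range", "blood_range", "iodine_range", "radius_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be nondecreasing")
        if self.lesion_count_range[0] < 1:
            raise ValueError("at least one lesion per case")

    @property
    def rank(self) -> int:
        return len(self.grid_shape)


@dataclass
class PairedCase:
    """One matched (SECT, VNC, IOM) triplet with lesion ground truth."""

    sect: np.ndarray
    vnc: np.ndarray
    iom: np.ndarray
    lesion_mask: np.ndarray
    lesions: list[LesionSpec]
    case_label: str
    case_id: str
    seed: int
    voxel_spacing: tuple[float, ...]
    mixing_coefficient: float = 1.0

    def __post_init__(self):
        shapes = {self.sect.shape, self.vnc.shape, self.iom.shape, self.lesion_mask.shape}
        if len(shapes) != 1:
            raise ValueError("sect/vnc/iom/mask must share one shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.sect.shape


def brain_mask(config: PhantomConfig) -> np.ndarray:
    """Elliptical 'brain' support: semi-axes 0.42 of each grid dimension."""
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in config.grid_shape],
                        indexing="ij")
    q = np.zeros(config.grid_shape)
    for g, n in zip(grids, config.grid_shape):
        c, a = (n - 1) / 2.0, 0.42 * n
        q += ((g - c) / a) ** 2
    return q <= 1.0


def _ellipsoid(shape: tuple[int, ...], center, radii) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    q = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        q += ((g - c) / r) ** 2
    return q <= 1.0


def _draw_kinds(config: PhantomConfig, n: int, positive: bool,
                rng: np.random.Generator) -> list[str]:
    kinds = [CS] * n
    if positive:
        primary = MIXED if rng.random() < config.mixed_fraction else ICH
        kinds[int(rng.integers(n))] = primary
    return kinds


def sample_lesions(config: PhantomConfig, rng: np.random.Generator,
                   force_label: str | None = None,
                   max_retries: int = 500) -> list[LesionSpec]:
    """Draw lesion specs for one case.

    The case is ICH-positive with probability ``class_prevalence`` (or forced
    via ``force_label``); positive cases contain exactly one blood-bearing
    lesion, any others are contrast staining.  Placement is rejection-sampled
    so each lesion (including its soft margin) lies inside the brain and does
    not collide with previously placed lesions.
    """
    mask = brain_mask(config)
    lo, hi = config.lesion_count_range
    n = int(rng.integers(lo, hi + 1))
    if force_label is None:
        positive = rng.random() < config.class_prevalence
    else:
        positive = force_label == ICH
    kinds = _draw_kinds(config, n, positive, rng)

    occupied = np.zeros(config.grid_shape, dtype=bool)
    specs: list[LesionSpec] = []
    for kind in kinds:
        margin = (config.ich_edge_sigma if kind in (ICH, MIXED)
                  else config.cs_edge_sigma)
        placed = False
        for _ in range(max_retries):
            radii = tuple(rng.uniform(*config.radius_range) for _ in config.grid_shape)
            if any(r + margin >= s - 1 - r - margin
                   for r, s in zip(radii, config.grid_shape)):
                continue  # lesion cannot fit on this grid at all
            center = tuple(rng.uniform(r + margin, s - 1 - r - margin)
                           for r, s in zip(radii, config.grid_shape))
            support = _ellipsoid(config.grid_shape, center,
                                 tuple(r + margin for r in radii))
            if np.all(mask[support]) and not np.any(occupied & support):
                occupied |= support
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place a {kind} lesion after {max_retries} retries")
        blood = rng.uniform(*config.blood_range) if kind in (ICH, MIXED) else 0.0
        iodine = (rng.uniform(*config.iodine_range)
                  if kind in (CS, MIXED) else 0.0)
        specs.append(LesionSpec(center=center, radii=radii, kind=kind,
                                blood_intensity=blood, iodine_intensity=iodine))
    return specs


def _lesion_profiles(spec: LesionSpec, config: PhantomConfig,
                     rng: np.random.Generator,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (blood_profile, iodine_profile, halo_profile).

    Blood/iodine profiles are normalized to unit mean over the lesion
    ellipsoid, so the mean intensity a lesion adds within its own support
    equals its material intensity regardless of margin sharpness — SECT
    brightness inside the lesion then carries no class information.

    Iodine-bearing lesions additionally produce a halo profile: a smooth
    ring beyond the lesion margin (zero underneath the lesion itself) that
    models the hypodense non-enhancing rim of the infarcted territory the
    staining sits in.  The halo is the spatial-context cue a reader (or
    network) can exploit on single-energy images.
    """
    support = _ellipsoid(config.grid_shape, spec.center, spec.radii)
    indicator = support.astype(float)
    blood = np.zeros_like(indicator)
    iodine = np.zeros_like(indicator)
    halo = np.zeros_like(indicator)
    if spec.blood_intensity > 0:
        sharp = gaussian_filter(indicator, config.ich_edge_sigma)
        texture = gaussian_filter(rng.standard_normal(config.grid_shape),
                                  config.texture_corr_sigma)
        texture *= config.ich_texture_sd / max(texture.std(), 1e-12)
        blood = sharp * np.clip(1.0 + texture, 0.2, None)
        blood /= max(blood[support].mean(), 1e-12)
    elif spec.iodine_intensity > 0:
        # draw (and discard) the texture field so the rng stream advances
        # identically for every lesion kind — keeps cohorts replayable when
        # only kinds differ
        rng.standard_normal(config.grid_shape)
    if spec.iodine_intensity > 0:
        iodine = gaussian_filter(indicator, config.cs_edge_sigma)
        iodine /= max(iodine[support].mean(), 1e-12)
        if config.halo_depth > 0:
            outer = _ellipsoid(config.grid_shape, spec.center,
                               tuple(r + config.halo_width for r in spec.radii))
            ring = (outer & ~support).astype(float)
            halo = gaussian_filter(ring, config.halo_sigma)
            halo[support] = 0.0  # never under the lesion: intensities stay matched
    return blood, iodine, halo


def render_case(lesions: list[LesionSpec], config: PhantomConfig,
                rng: np.random.Generator, case_id: str = "case",
                seed: int = 0) -> PairedCase:
    """Rasterize lesion specs into a matched (SECT, VNC, IOM) triplet.

    VNC = textured brain background + blood contributions; IOM = iodine
    contributions on a zero background; SECT follows the forward model with
    optional blur and Gaussian noise, clipped to the intensity range.
    """
    mask = brain_mask(config)
    texture = gaussian_filter(rng.standard_normal(config.grid_shape), 3.0)
    texture *= config.background_sd / max(texture.std(), 1e-12)
    vnc = np.where(mask, config.background_mean + texture, 0.0)
    iom = np.zeros(config.grid_shape)
    lesion_mask = np.zeros(config.grid_shape, dtype=np.int32)

    for i, spec in enumerate(lesions, start=1):
        blood, iodine, halo = _lesion_profiles(spec, config, rng)
        vnc = vnc + spec.blood_intensity * blood
        vnc = vnc - config.halo_depth * halo * mask  # infarct rim, brain only
        iom = iom + spec.iodine_intensity * iodine
        lesion_mask[_ellipsoid(config.grid_shape, spec.center, spec.radii)] = i

    vnc = np.clip(vnc, *INTENSITY_RANGE)
    iom = np.clip(iom, *INTENSITY_RANGE)
    sect = vnc + config.mixing_coefficient * iom
    if config.blur_sigma > 0:
        sect = gaussian_filter(sect, config.blur_sigma)
    if config.noise_sd > 0:
        sect = sect + config.noise_sd * rng.standard_normal(config.grid_shape)
    sect = np.clip(sect, *INTENSITY_RANGE)

    label = ICH if any(s.kind in (ICH, MIXED) for s in lesions) else CS
    return PairedCase(sect=sect, vnc=vnc, iom=iom, lesion_mask=lesion_mask,
                      lesions=list(lesions), case_label=label, case_id=case_id,
                      seed=seed, voxel_spacing=tuple(config.voxel_spacing),
                      mixing_coefficient=config.mixing_coefficient)


def simulate_case(config: PhantomConfig, seed: int, case_id: str | None = None,
                  force_label: str | None = None) -> PairedCase:
    rng = np.random.default_rng(seed)
    lesions = sample_lesions(config, rng, force_label=force_label)
    return render_case(lesions, config, rng,
                       case_id=case_id or f"case_{seed:06d}", seed=seed)


def simulate_cohort(config: PhantomConfig, n: int, seed: int | None = None,
                    n_positive: int | None = None) -> list[PairedCase]:
    """Simulate ``n`` independent cases.

    ``n_positive`` fixes the exact number of ICH-positive cases (their order
    shuffled); by default each case is positive independently with probability
    ``class_prevalence``.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    case_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(n)]
    labels: list[str | None]
    if n_positive is None:
        labels = [None] * n
    else:
        if not 0 <= n_positive <= n:
            raise ValueError("n_positive out of range")
        labels = [ICH] * n_positive + [CS] * (n - n_positive)
        np.random.default_rng(root.generate_state(1)[0]).shuffle(labels)
    return [simulate_case(config, s, case_id=f"case_{i:04d}", force_label=lab)
            for i, (s, lab) in enumerate(zip(case_seeds, labels))]


def _background_level(vnc_like: np.ndarray, lesion_mask: np.ndarray) -> float:
    outside = lesion_mask == 0
    vals = vnc_like[outside]
    tissue = vals[vals > 0.05 * vnc_like.max()]
    return float(np.median(tissue if tissue.size else vals))


def decomposition_score(vnc_like: np.ndarray, lesion_mask: np.ndarray) -> float:
    """Largest mean VNC elevation over background across lesions.

    This is the continuous statistic behind the dual-energy reading rule:
    blood persists on (s)VNC, iodine does not.
    """
    if vnc_like.shape != lesion_mask.shape:
        raise ValueError("shape mismatch between volume and lesion mask")
    labels = np.unique(lesion_mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("empty lesion mask")
    bg = _background_level(vnc_like, lesion_mask)
    return max(float(vnc_like[lesion_mask == lab].mean()) - bg for lab in labels)


def classify_by_decomposition(vnc_like: np.ndarray, iom_like: np.ndarray,
                              lesion_mask: np.ndarray,
                              threshold: float = 20.0) -> str:
    """Dual-energy reading rule: ICH iff some lesion stays elevated on VNC.

    ``iom_like`` is accepted for interface symmetry with the clinical reading
    (both maps are inspected) but the binary criterion rests on the VNC
    elevation alone.
    """
    if iom_like is not None and iom_like.shape != vnc_like.shape:
        raise ValueError("vnc/iom shape mismatch")
    return ICH if decomposition_score(vnc_like, lesion_mask) > threshold else CS


def stratified_split(cases: list[PairedCase], ratio: tuple[int, int] = (4, 1),
                     seed: int = 0) -> tuple[list[PairedCase], list[PairedCase]]:
    """Deterministic per-class (stratified) train/validation partition.

    Per class, the validation count is ``round(class_n * ratio_val /
    (ratio_train + ratio_val))``; membership is a seeded shuffle.
    """
    by_class: dict[str, list[PairedCase]] = {}
    for c in cases:
        by_class.setdefault(c.case_label, []).append(c)
    if len(by_class) < 2:
        raise ValueError("both classes must be present to stratify")
    for label, members in by_class.items():
        if len(members) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 members")
    frac_val = ratio[1] / (ratio[0] + ratio[1])
    rng = np.random.default_rng(seed)
    train: list[PairedCase] = []
    val: list[PairedCase] = []
    for label in sorted(by_class):
        members = by_class[label]
        order = rng.permutation(len(members))
        n_val = round(len(members) * frac_val)
        val.extend(members[i] for i in order[:n_val])
        train.extend(members[i] for i in order[n_val:])
    return train, val


# -- NIfTI / manifest I/O -----------------------------------------------------

def _affine(spacing: tuple[float, ...]) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(spacing[:3]):
        aff[i, i] = s
    return aff


def _as_3d(volume: np.ndarray) -> np.ndarray:
    return volume[..., None] if volume.ndim == 2 else volume


def save_case(case: PairedCase, out_dir: str | Path) -> dict[str, str]:
    """Write the four volumes as .nii.gz; returns the file map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(case.voxel_spacing)
    paths = {}
    for name, vol in (("sect", case.sect), ("vnc", case.vnc),
                      ("iom", case.iom), ("mask", case.lesion_mask.astype(np.int16))):
        p = out_dir / f"{case.case_id}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(_as_3d(np.asarray(vol)), aff), p)
        paths[name] = str(p)
    return paths


def load_case(row: pd.Series | dict) -> PairedCase:
    """Rebuild a PairedCase from a manifest row (lesion specs are not stored)."""
    def _read(path):
        img = nib.load(path)
        arr = np.asarray(img.dataobj, dtype=np.float64)
        return np.squeeze(arr, axis=-1) if arr.shape[-1] == 1 else arr

    sect, vnc, iom = (_read(row[k]) for k in ("path_sect", "path_vnc", "path_iom"))
    mask = _read(row["path_mask"]).astype(np.int32)
    img = nib.load(row["path_sect"])
    spacing = tuple(float(z) for z in img.header.get_zooms()[:sect.ndim])
    return PairedCase(sect=sect, vnc=vnc, iom=iom, lesion_mask=mask, lesions=[],
                      case_label=str(row["case_label"]), case_id=str(row["case_id"]),
                      seed=int(row.get("seed", 0)), voxel_spacing=spacing,
                      mixing_coefficient=float(row.get("mixing_coefficient", 1.0)))


def write_manifest(cases: list[PairedCase], out_dir: str | Path,
                   split: dict[str, str] | None = None) -> pd.DataFrame:
    """Save all cases plus a manifest CSV; returns the manifest frame."""
    out_dir = Path(out_dir)
    rows = []
    for case in cases:
        paths = save_case(case, out_dir / "volumes")
        rows.append({
            "case_id": case.case_id, "case_label": case.case_label,
            "seed": case.seed, "mixing_coefficient": case.mixing_coefficient,
            "split": (split or {}).get(case.case_id, ""),
            "path_sect": paths["sect"], "path_vnc": paths["vnc"],
            "path_iom": paths["iom"], "path_mask": paths["mask"],
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
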