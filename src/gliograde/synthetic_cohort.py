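"""Synthetic histology-like cohort generator.

Emulates the image contrasts that separate low-grade (LGG, WHO II-III) from
high-grade (HGG, WHO IV) glioma on H&E-stained slides, in grayscale: darker
elliptical nuclei on a brighter stromal background.  High-grade patches have
more, larger and less circular nuclei, stronger intensity heterogeneity
(higher GLCM contrast/entropy), jagged nuclear boundaries, and occasional
necrosis-like bright holes.  The clinical table carries an age gap between
the classes and an (by default uninformative) gender column.

Everything is deterministic given the seed, so every downstream stage of the
grading pipeline can be tested end-to-end without any slide archive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import polygon

__all__ = [
    "ClassParams",
    "CohortConfig",
    "LGG_PARAMS",
    "HGG_PARAMS",
    "generate_patch",
    "generate_slide",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class ClassParams:
    """Image-generation parameters for one histologic grade.

    nucleus_density is the expected nucleus count per 10,000 pixels (a
    100 x 100 region), so patch sizes can change without re-tuning counts.
    Intensities are on the 8-bit scale.
    """

    nucleus_density: float = 8.0
    nucleus_major_axis_mean: float = 16.0
    nucleus_axis_ratio_mean: float = 1.3
    nucleus_intensity_mean: float = 90.0
    stroma_intensity_mean: float = 200.0
    heterogeneity_noise_sd: float = 8.0
    necrosis_hole_rate: float = 0.0
    edge_jaggedness: float = 0.05

    def __post_init__(self) -> None:
        for name in ("nucleus_intensity_mean", "stroma_intensity_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.nucleus_density < 0:
            raise ValueError("nucleus_density must be >= 0")
        if self.nucleus_axis_ratio_mean < 1.0:
            raise ValueError("nucleus_axis_ratio_mean must be >= 1")
        if self.heterogeneity_noise_sd < 0:
            raise ValueError("heterogeneity_noise_sd must be >= 0")
        if not 0.0 <= self.necrosis_hole_rate <= 1.0:
            raise ValueError("necrosis_hole_rate must be a probability")
        if self.edge_jaggedness < 0:
            raise ValueError("edge_jaggedness must be >= 0")


#: Default low-grade parameters: sparser, smaller, rounder, smoother nuclei;
#: mild heterogeneity; no necrosis.
LGG_PARAMS = ClassParams()

#: Default high-grade parameters: denser, larger, elongated nuclei with
#: jagged boundaries, strong heterogeneity and necrosis-like holes.
HGG_PARAMS = ClassParams(
    nucleus_density=14.0,
    nucleus_major_axis_mean=24.0,
    nucleus_axis_ratio_mean=2.0,
    nucleus_intensity_mean=70.0,
    stroma_intensity_mean=200.0,
    heterogeneity_noise_sd=20.0,
    necrosis_hole_rate=0.3,
    edge_jaggedness=0.25,
)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation parameters.

    Class mixture and clinical defaults follow the study population this
    generator emulates: 386/735 low-grade vs 349/735 high-grade patients,
    mean ages ~43 (weighted over WHO II-III) vs 56.79 years, 58% male.
    """

    n_patients: int = 735
    hgg_fraction: float = 349 / 735
    patches_per_patient: int = 100
    patch_size: int = 1024
    lgg_params: ClassParams = field(default_factory=lambda: LGG_PARAMS)
    hgg_params: ClassParams = field(default_factory=lambda: HGG_PARAMS)
    age_mean_lgg: float = 43.19
    age_mean_hgg: float = 56.79
    age_sd: float = 10.0
    male_fraction: float = 427 / 735
    gender_grade_logodds: float = 0.0
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        """Load a config from JSON or a flat ``key=value`` file.

        Nested ``lgg_params``/``hgg_params`` mappings (JSON) or dotted keys
        like ``lgg_params.nucleus_density=8`` (flat) override the defaults.
        """
        import json as _json

        text = Path(path).read_text()
        try:
            raw = _json.loads(text)
        except _json.JSONDecodeError:
            raw = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        kwargs: dict = {}
        params: dict[str, dict] = {"lgg_params": {}, "hgg_params": {}}
        for key, value in raw.items():
            if key in params and isinstance(value, dict):
                params[key] = value
            elif "." in key and key.split(".", 1)[0] in params:
                side, field_name = key.split(".", 1)
                params[side][field_name] = float(value)
            elif key == "seed" or key in ("n_patients", "patches_per_patient",
                                          "patch_size"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        for side, default in (("lgg_params", LGG_PARAMS), ("hgg_params", HGG_PARAMS)):
            if params[side]:
                kwargs[side] = dataclasses.replace(
                    default, **{k: float(v) for k, v in params[side].items()})
        return cls(**kwargs)

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.hgg_fraction < 1.0:
            raise ValueError("hgg_fraction must be strictly between 0 and 1")
        if self.patches_per_patient < 1:
            raise ValueError("patches_per_patient must be >= 1")
        if self.patch_size < 64:
            raise ValueError("patch_size must be >= 64")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be a proportion")


def _jagged_radii(base: np.ndarray, jaggedness: float, rng: np.random.Generator,
                  n_vertices: int) -> np.ndarray:
    """Perturb boundary radii with smooth periodic noise.

    A low-order random Fourier series in the polar angle keeps the boundary
    closed and smooth; its amplitude scales with ``jaggedness`` (relative to
    the local radius).
    """
    if jaggedness <= 0:
        return base
    phi = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    wobble = np.zeros(n_vertices)
    for k in range(2, 6):
        a, b = rng.normal(0.0, 1.0 / k, size=2)
        wobble += a * np.cos(k * phi) + b * np.sin(k * phi)
    return base * np.clip(1.0 + jaggedness * wobble, 0.2, None)


def _draw_blob(img: np.ndarray, center: tuple[float, float], semi_major: float,
               semi_minor: float, theta: float, value: float,
               jaggedness: float, rng: np.random.Generator) -> None:
    """Rasterize one (possibly jagged) filled ellipse into ``img`` in place."""
    n_vertices = 48
    phi = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    # polar radius of an ellipse with semi-axes (a, b)
    a, b = semi_major, semi_minor
    r = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    r = _jagged_radii(r, jaggedness, rng, n_vertices)
    rows = center[0] + r * np.sin(phi + theta)
    cols = center[1] + r * np.cos(phi + theta)
    rr, cc = polygon(rows, cols, shape=img.shape)
    img[rr, cc] = value


def generate_patch(params: ClassParams, patch_size: int = 1024,
                   rng_seed: int = 0) -> np.ndarray:
    """Generate one grayscale patch (uint8, ``patch_size`` square).

    Nuclei are filled ellipses darker than the stroma, with orientation
    uniform on [0, pi), count Poisson-distributed at the configured density,
    and boundaries roughened by ``edge_jaggedness``.  Optional necrosis-like
    bright holes and i.i.d. Gaussian noise are added on top.  Bit-identical
    output for identical (params, patch_size, rng_seed).
    """
    if patch_size < 64:
        raise ValueError("patch_size must be >= 64")
    rng = np.random.default_rng(rng_seed)
    img = np.full((patch_size, patch_size), float(np.round(params.stroma_intensity_mean)))

    n_nuclei = rng.poisson(params.nucleus_density * patch_size * patch_size / 1e4)
    for _ in range(n_nuclei):
        center = rng.uniform(0, patch_size, size=2)
        major = max(3.0, rng.normal(params.nucleus_major_axis_mean,
                                    0.15 * params.nucleus_major_axis_mean))
        ratio = max(1.0, rng.normal(params.nucleus_axis_ratio_mean,
                                    0.10 * params.nucleus_axis_ratio_mean))
        theta = rng.uniform(0.0, np.pi)
        value = np.clip(rng.normal(params.nucleus_intensity_mean, 6.0), 0, 255)
        _draw_blob(img, (center[0], center[1]), major / 2.0, major / (2.0 * ratio),
                   theta, value, params.edge_jaggedness, rng)

    if rng.random() < params.necrosis_hole_rate:
        # one bright, ragged necrotic focus covering a few percent of the patch
        center = rng.uniform(0.2 * patch_size, 0.8 * patch_size, size=2)
        radius = rng.uniform(0.08, 0.16) * patch_size
        _draw_blob(img, (center[0], center[1]), radius, radius * 0.8,
                   rng.uniform(0.0, np.pi), 240.0,
                   max(0.3, params.edge_jaggedness), rng)

    if params.heterogeneity_noise_sd > 0:
        img += rng.normal(0.0, params.heterogeneity_noise_sd, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_slide(params: ClassParams, height: int, width: int,
                   rng_seed: int = 0, background: float = 245.0,
                   tissue_fraction: float = 1.0) -> np.ndarray:
    """Generate a slide-like image: tissue texture over near-white glass.

    ``tissue_fraction`` < 1 leaves the right-hand part of the slide as blank
    background, emulating the glass margin of a scanned section, so that the
    patch extractor's tissue filter has something to reject.
    """
    rng = np.random.default_rng(rng_seed)
    img = np.full((height, width), float(np.round(background)))
    tissue_cols = int(round(width * tissue_fraction))
    if tissue_cols > 0:
        tissue = generate_patch(
            params,
            patch_size=max(64, max(height, tissue_cols)),
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        img[:, :tissue_cols] = tissue[:height, :tissue_cols]
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_cohort(config: CohortConfig) -> tuple[dict[str, list[np.ndarray]], pd.DataFrame]:
    """Generate per-patient patch sets and the clinical table.

    Returns ``(patches, clinical)`` where ``patches`` maps patient_id to a
    list of ``patches_per_patient`` grayscale patches drawn from that
    patient's class parameters, and ``clinical`` has columns
    ``patient_id, age, gender, grade``.
    """
    n = config.n_patients
    n_hgg = int(round(n * config.hgg_fraction))
    if n_hgg <= 0 or n_hgg >= n:
        raise ValueError("cohort must contain both classes; adjust n_patients/hgg_fraction")

    rng = np.random.default_rng(config.seed)
    grades = np.array(["HGG"] * n_hgg + ["LGG"] * (n - n_hgg))
    rng.shuffle(grades)

    records = []
    patches: dict[str, list[np.ndarray]] = {}
    logit_male = np.log(config.male_fraction / (1.0 - config.male_fraction)) \
        if 0.0 < config.male_fraction < 1.0 else np.inf * np.sign(config.male_fraction - 0.5)
    for i, grade in enumerate(grades):
        pid = f"P{i + 1:04d}"
        is_hgg = grade == "HGG"
        params = config.hgg_params if is_hgg else config.lgg_params
        age_mean = config.age_mean_hgg if is_hgg else config.age_mean_lgg
        age = float(np.clip(rng.normal(age_mean, config.age_sd), 18.0, 95.0))
        shift = config.gender_grade_logodds * (0.5 if is_hgg else -0.5)
        p_male = 1.0 / (1.0 + np.exp(-(logit_male + shift)))
        gender = "male" if rng.random() < p_male else "female"
        records.append({"patient_id": pid, "age": age, "gender": gender, "grade": grade})
        patches[pid] = [
            generate_patch(params, config.patch_size, int(rng.integers(0, 2**31 - 1)))
            for _ in range(config.patches_per_patient)
        ]
    clinical = pd.DataFrame.from_records(records)
    return patches, clinical


def write_cohort(patches: dict[str, list[np.ndarray]], clinical: pd.DataFrame,
                 outdir: str | Path) -> Path:
    """Write patches as 8-bit grayscale PNGs and the clinical table as CSV."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    patch_dir = outdir / "patches"
    patch_dir.mkdir(parents=True, exist_ok=True)
    for pid, plist in patches.items():
        for j, patch in enumerate(plist):
            iio.imwrite(patch_dir / f"{pid}_patch{j:03d}.png", patch)
    clinical.to_csv(outdir / "clinical.csv", index=False)
    return outdir
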