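"""Synthetic blastocyst phantoms with ground-truth masks and outcomes.

Real blastocyst micrograph cohorts with known pregnancy outcomes are
access-restricted, so this module generates phantoms that emulate their
structure: a day-5/6 blastocyst is rendered as three nested elliptical
regions — the zona pellucida (ZP) annulus outermost, the trophectoderm
(TE) annulus inside it and the inner area (blastocoel + inner cell
mass) at the centre — each with its own texture (mean intensity plus
Gaussian-smoothed noise), on a darker background.

Cohorts emulate the structure of the clinical databases this pipeline
targets: two calibration regimes standing in for the 20x and 40x
microscope objectives, a nominal embryo diameter of 180 µm, patient
ages around 34.4 ± 5.5 years and a positive b-hCG prevalence near 53%.

The pregnancy-test outcome is drawn from a stated logistic model on
per-sample latent values (ZP thickness, TE texture SD, age — each
standardized against its cohort-level distribution), so that the
strength of the image→outcome signal is an explicit, testable knob:
with all coefficients zero the labels are pure noise; with large
coefficients downstream classifiers must recover the signal.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from . import annotation_io
from .containers import Micrograph, RegionMasks

__all__ = [
    "RegionTexture",
    "PhantomSpec",
    "PhantomSample",
    "Cohort",
    "CALIBRATION_REGIMES",
    "LATENT_NAMES",
    "generate_phantom",
    "assign_outcome",
    "generate_cohort",
]

#: µm/px of the two emulated microscope objectives.
CALIBRATION_REGIMES = {"20x": 0.5, "40x": 0.25}

LATENT_NAMES = ("zp_thickness", "te_texture_sd", "age")


@dataclass(frozen=True)
class RegionTexture:
    """Texture of one rendered region.

    mean
        Mean 8-bit intensity of the region.
    noise_sd
        SD of the additive noise field (8-bit units); 0 renders the
        region perfectly flat.
    smoothing_px
        Gaussian correlation length of the noise field in pixels.
    """

    mean: float
    noise_sd: float
    smoothing_px: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.mean <= 255:
            raise ValueError(f"texture mean {self.mean} outside [0, 255]")
        if self.noise_sd < 0:
            raise ValueError(f"noise SD must be >= 0, got {self.noise_sd}")
        if self.smoothing_px < 0:
            raise ValueError("smoothing length must be >= 0")


def _default_textures() -> dict[str, RegionTexture]:
    return {
        "background": RegionTexture(mean=45, noise_sd=6, smoothing_px=2),
        "inner": RegionTexture(mean=85, noise_sd=12, smoothing_px=3),
        "te": RegionTexture(mean=135, noise_sd=22, smoothing_px=2),
        "zp": RegionTexture(mean=195, noise_sd=10, smoothing_px=2),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of a phantom cohort.

    ``image_size`` of ``None`` sizes the frame automatically so the
    embryo fits with a 15% margin at the given calibration.
    ``outcome_coeffs`` maps latent names (and ``"intercept"``) to
    logistic-regression coefficients on the standardized latents; a
    missing intercept defaults to ``logit(prevalence_target)``.
    """

    image_size: Optional[tuple[int, int]] = None
    microns_per_pixel: float = CALIBRATION_REGIMES["20x"]
    embryo_diameter_um: float = 180.0
    zp_thickness_um: float = 18.0
    te_thickness_um: float = 16.0
    region_texture: dict[str, RegionTexture] = field(default_factory=_default_textures)
    age_mean_years: float = 34.4
    age_sd_years: float = 5.5
    outcome_coeffs: dict[str, float] = field(default_factory=dict)
    prevalence_target: float = 0.5298
    eccentricity: float = 0.25
    #: per-sample biological variation of the latent-bearing quantities
    zp_thickness_sd_um: float = 3.5
    te_noise_sd_jitter: float = 7.0

    def __post_init__(self) -> None:
        if self.zp_thickness_um <= 0 or self.te_thickness_um <= 0:
            raise ValueError("region thicknesses must be positive")
        if self.zp_thickness_um + self.te_thickness_um >= self.embryo_diameter_um / 2:
            raise ValueError(
                "zp_thickness_um + te_thickness_um must be < embryo radius"
            )
        if not 0 <= self.eccentricity < 1:
            raise ValueError("eccentricity must lie in [0, 1)")
        if not 0 <= self.prevalence_target <= 1:
            raise ValueError("prevalence_target must lie in [0, 1]")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be positive")
        missing = {"background", "inner", "te", "zp"} - set(self.region_texture)
        if missing:
            raise ValueError(f"region_texture missing regions {sorted(missing)}")
        unknown = set(self.outcome_coeffs) - set(LATENT_NAMES) - {"intercept"}
        if unknown:
            raise ValueError(f"unknown outcome coefficient names {sorted(unknown)}")
        if self.image_size is None:
            extent = math.ceil(
                1.15 * self.embryo_diameter_um / self.microns_per_pixel)
            object.__setattr__(self, "image_size", (extent, extent))

    def effective_coeffs(self) -> dict[str, float]:
        coeffs = dict(self.outcome_coeffs)
        coeffs.setdefault("intercept", float(logit(self.prevalence_target)))
        return coeffs


@dataclass(frozen=True)
class PhantomSample:
    """One generated phantom with its ground truth."""

    micrograph: Micrograph
    masks: RegionMasks
    age_years: float
    bhcg_mUI_per_mL: float
    latent: dict[str, float]
    seed_used: int

    def __post_init__(self) -> None:
        if self.bhcg_mUI_per_mL < 0:
            raise ValueError("b-hCG must be >= 0")

    @property
    def label(self) -> int:
        return annotation_io.label_outcome(self.bhcg_mUI_per_mL)


@dataclass(frozen=True)
class Cohort:
    samples: list[PhantomSample]
    manifest: pd.DataFrame


def _noise_field(rng: np.random.Generator, shape: tuple[int, int],
                 sd: float, smoothing_px: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    g = rng.standard_normal(shape)
    if smoothing_px > 0:
        g = gaussian_filter(g, smoothing_px)
        g /= g.std()  # restore unit variance lost to smoothing
    return g * sd


def _ellipse_interior(shape: tuple[int, int], center: tuple[float, float],
                      semi_axes: tuple[float, float], theta: float) -> np.ndarray:
    """Boolean mask of pixel centres inside a rotated ellipse."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    dx = xs - center[0]
    dy = ys - center[1]
    u = math.cos(theta) * dx + math.sin(theta) * dy
    v = -math.sin(theta) * dx + math.cos(theta) * dy
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomSample:
    """Render one phantom blastocyst; deterministic for fixed (spec, seed)."""
    rng = np.random.default_rng(seed)
    h, w = spec.image_size
    mpp = spec.microns_per_pixel

    # per-sample biology: ZP thickness, TE texture SD, age
    zp_t = float(rng.normal(spec.zp_thickness_um, spec.zp_thickness_sd_um)) \
        if spec.zp_thickness_sd_um > 0 else spec.zp_thickness_um
    zp_t = float(np.clip(
        zp_t, 2 * mpp,
        spec.embryo_diameter_um / 2 - spec.te_thickness_um - 4 * mpp))
    te_tex = spec.region_texture["te"]
    if te_tex.noise_sd > 0 and spec.te_noise_sd_jitter > 0:
        te_sd = float(max(0.5, rng.normal(te_tex.noise_sd,
                                          spec.te_noise_sd_jitter)))
    else:
        te_sd = te_tex.noise_sd
    age = float(np.clip(rng.normal(spec.age_mean_years, spec.age_sd_years),
                        18.0, 50.0))

    latent = {
        "zp_thickness": (zp_t - spec.zp_thickness_um)
        / max(spec.zp_thickness_sd_um, 1e-9),
        "te_texture_sd": (te_sd - te_tex.noise_sd)
        / max(spec.te_noise_sd_jitter, 1e-9),
        "age": (age - spec.age_mean_years) / max(spec.age_sd_years, 1e-9),
    }

    # geometry: three nested ellipses of constant wall thickness
    a_um = spec.embryo_diameter_um / 2
    b_um = a_um * math.sqrt(1 - spec.eccentricity ** 2)
    theta = float(rng.uniform(0, math.pi))
    jitter = 0.02 * min(h, w)
    center = (w / 2 + float(rng.uniform(-jitter, jitter)),
              h / 2 + float(rng.uniform(-jitter, jitter)))
    boundaries_um = [
        (a_um, b_um),
        (a_um - zp_t, b_um - zp_t),
        (a_um - zp_t - spec.te_thickness_um, b_um - zp_t - spec.te_thickness_um),
    ]
    if boundaries_um[-1][0] <= 0 or boundaries_um[-1][1] <= 0:
        raise ValueError("region thicknesses leave no inner area")
    half_diag = a_um / mpp
    if (center[0] - half_diag < -0.5 or center[0] + half_diag > w - 0.5 or
            center[1] - half_diag < -0.5 or center[1] + half_diag > h - 0.5):
        raise ValueError(
            f"embryo of diameter {spec.embryo_diameter_um} um at "
            f"{mpp} um/px does not fit the {h}x{w} frame"
        )

    interiors = [
        _ellipse_interior((h, w), center, (au / mpp, bu / mpp), theta)
        for au, bu in boundaries_um
    ]
    masks = RegionMasks(
        zp=interiors[0] & ~interiors[1],
        te=interiors[1] & ~interiors[2],
        inner=interiors[2],
    )
    masks.require_nonempty()

    # render: per-region mean + smoothed noise, composed by mask
    img = np.empty((h, w), dtype=float)
    region_masks = {
        "background": ~interiors[0],
        "zp": masks.zp,
        "te": masks.te,
        "inner": masks.inner,
    }
    for name in ("background", "zp", "te", "inner"):
        tex = spec.region_texture[name]
        sd = te_sd if name == "te" else tex.noise_sd
        fld = tex.mean + _noise_field(rng, (h, w), sd, tex.smoothing_px)
        img[region_masks[name]] = fld[region_masks[name]]
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    outcome_seed = int(rng.integers(0, 2 ** 31))
    bhcg = assign_outcome(latent, spec.effective_coeffs(), outcome_seed)

    return PhantomSample(
        micrograph=Micrograph(pixels=pixels, microns_per_pixel=mpp),
        masks=masks,
        age_years=age,
        bhcg_mUI_per_mL=bhcg,
        latent=latent,
        seed_used=int(seed),
    )


def assign_outcome(latent: dict[str, float], coeffs: dict[str, float],
                   seed: int) -> float:
    """Draw a b-hCG concentration from the logistic outcome model.

    The positive/negative state is Bernoulli with probability
    ``expit(intercept + sum(coeff * latent))``; positives then draw a
    lognormal concentration at or above the 20 mUI/mL decision
    threshold, negatives strictly below it.
    """
    unknown = [k for k in coeffs if k != "intercept" and k not in latent]
    if unknown:
        raise KeyError(f"unknown outcome coefficient names {unknown}")
    eta = coeffs.get("intercept", 0.0) + sum(
        c * latent[k] for k, c in coeffs.items() if k != "intercept"
    )
    rng = np.random.default_rng(seed)
    positive = rng.random() < expit(eta)
    thr = annotation_io.BHCG_POSITIVE_THRESHOLD
    if positive:
        return float(thr * math.exp(abs(rng.normal(1.2, 0.8))))
    return float(min(thr * math.exp(-abs(rng.normal(1.4, 0.9))), thr - 1e-3))


def _sample_seed(master_seed: int, index: int) -> int:
    """Stable per-sample seed derived from (master seed, sample index)."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_cohort(
    spec: PhantomSpec,
    n: int,
    seed: int,
    objective_counts: Optional[dict[str, int]] = None,
    out_dir: Optional[str | Path] = None,
    exact_prevalence: bool = False,
) -> Cohort:
    """Generate ``n`` independent phantoms with a cohort manifest.

    ``objective_counts`` fixes how many samples use each calibration
    regime (e.g. ``{"20x": 90, "40x": 44}``); by default samples are
    split 2:1 between the 20x and 40x regimes in sequence order. With
    ``out_dir`` the images, label masks and manifest CSV are written to
    disk in the formats the cohort loader reads.

    With ``exact_prevalence`` the number of positives is fixed at the
    expected count under the outcome model instead of being drawn
    binomially: positive status is assigned by Gumbel-top-k sampling on
    the per-sample logistic scores, which preserves the model's
    ordering (higher-score samples are more likely positive) while
    pinning the class balance — useful when a cohort must match a
    stated prevalence exactly.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if objective_counts is None:
        n20 = round(n * 2 / 3)
        objective_counts = {"20x": n20, "40x": n - n20}
    unknown = set(objective_counts) - set(CALIBRATION_REGIMES)
    if unknown:
        raise ValueError(f"unknown objectives {sorted(unknown)}")
    if sum(objective_counts.values()) != n:
        raise ValueError(
            f"objective counts {objective_counts} do not sum to n={n}")
    objectives = [
        obj for obj in CALIBRATION_REGIMES
        for _ in range(objective_counts.get(obj, 0))
    ]

    samples: list[PhantomSample] = []
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    for i in range(n):
        obj = objectives[i]
        mpp = CALIBRATION_REGIMES[obj]
        spec_i = spec if mpp == spec.microns_per_pixel else replace(
            spec, microns_per_pixel=mpp, image_size=None)
        sample_id = f"S{i:04d}"
        s = generate_phantom(spec_i, _sample_seed(seed, i))
        s = replace(
            s,
            micrograph=Micrograph(
                pixels=s.micrograph.pixels,
                microns_per_pixel=s.micrograph.microns_per_pixel,
                sample_id=sample_id,
            ),
        )
        samples.append(s)
        image_path = f"images/{sample_id}.png"
        mask_path = f"masks/{sample_id}.png"
        if out_dir is not None:
            annotation_io.write_micrograph(s.micrograph, out_dir / image_path)
            annotation_io.write_mask(s.masks, out_dir / mask_path)
        rows.append({
            "sample_id": sample_id,
            "image_path": image_path,
            "mask_path": mask_path,
            "age_years": s.age_years,
            "microns_per_pixel": mpp,
            "objective": obj,
            "bhcg_mUI_per_mL": s.bhcg_mUI_per_mL,
        })
    if exact_prevalence:
        samples = _pin_prevalence(spec, samples, seed)
        for row, s in zip(rows, samples):
            row["bhcg_mUI_per_mL"] = s.bhcg_mUI_per_mL

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        annotation_io.write_manifest(manifest, out_dir / "manifest.csv")
    return Cohort(samples=samples, manifest=manifest)


def _pin_prevalence(spec: PhantomSpec, samples: list[PhantomSample],
                    seed: int) -> list[PhantomSample]:
    """Re-draw outcomes so exactly round(sum p_i) samples are positive."""
    coeffs = spec.effective_coeffs()
    etas = np.array([
        coeffs.get("intercept", 0.0) + sum(
            c * s.latent[k] for k, c in coeffs.items() if k != "intercept")
        for s in samples
    ])
    n_pos = int(round(expit(etas).sum()))
    rng = np.random.default_rng(_sample_seed(seed, len(samples) + 1))
    scores = etas + rng.gumbel(size=len(samples))
    positive = np.zeros(len(samples), dtype=bool)
    positive[np.argsort(scores)[::-1][:n_pos]] = True
    thr = annotation_io.BHCG_POSITIVE_THRESHOLD
    out = []
    for s, pos in zip(samples, positive):
        if pos:
            bhcg = float(thr * math.exp(abs(rng.normal(1.2, 0.8))))
        else:
            bhcg = float(min(thr * math.exp(-abs(rng.normal(1.4, 0.9))),
                             thr - 1e-3))
        out.append(replace(s, bhcg_mUI_per_mL=bhcg))
    return out
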