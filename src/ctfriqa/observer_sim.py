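"""Synthetic study material: CT-like phantom slices and a simulated
observer panel for double-stimulus scoring.

The phantom generator emulates the three anatomical sites used as reference
material — head (brain tissue inside a high-attenuation skull rim), chest
(two air-filled lung fields with vessel-like texture inside a soft-tissue
wall), abdomen (soft-tissue organs around a dense spine) — with
site-plausible Hounsfield ranges, so site-specific display windows behave
as they would on real slices.

The observer model replaces the human panel: each distortion grid cell has
a latent quality (exponential decay to a plateau in the two distortion
intensities), each simulated observer carries a fixed additive bias, and
each mark adds independent within-observer noise, clipped to the 0-100
continuous scale.  A calibration routine tunes the mark noise until the
panel's inter-rater agreement matches a target ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .ct_prep import DEFAULT_HU_OFFSET, RawCTImage
from .distortions import BLUR_GRID, NOISE_GRID, DistortionSpec, grid_specs


@dataclass(frozen=True)
class PhantomSpec:
    site: str
    size: int = 512
    seed: int = 0
    texture_scale: float = 1.0
    hu_offset: int = DEFAULT_HU_OFFSET
    id: str | None = None

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("phantom size must be >= 64")

    @property
    def image_id(self) -> str:
        return self.id if self.id is not None else f"{self.site}{self.seed}"


@dataclass(frozen=True)
class ObserverModelParams:
    """Latent-quality and panel parameters for the simulated observers.

    ``floor`` is the subjective-score plateau deeply distorted images decay
    to; ``tau_noise`` / ``tau_blur`` are the decay constants (gray levels /
    pixels) of the two distortion axes; ``ref_mean`` is the average mark a
    pristine reference receives; ``bias_sd`` spreads a per-observer additive
    bias and ``mark_sd`` is the within-observer mark noise, both on the
    0-100 scale.
    """

    floor: float = 30.0
    tau_noise: float = 12.0
    tau_blur: float = 1.2
    ref_mean: float = 85.0
    bias_sd: float = 5.0
    mark_sd: float = 5.0
    n_observers: int = 6
    interaction: float = 0.0  # optional noise x blur interaction coefficient

    def __post_init__(self) -> None:
        if self.bias_sd < 0 or self.mark_sd < 0:
            raise ValueError("SDs must be >= 0")
        if not 0 <= self.floor < 100:
            raise ValueError("floor must lie in [0, 100)")
        if self.n_observers < 2:
            raise ValueError("need at least 2 observers")


def _ellipse(size: int, cy: float, cx: float, ry: float, rx: float, angle: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    y, x = yy - cy, xx - cx
    if angle:
        c, s = np.cos(angle), np.sin(angle)
        y, x = c * y - s * x, s * y + c * x
    return (y / ry) ** 2 + (x / rx) ** 2 <= 1.0


def _texture(rng: np.random.Generator, size: int, smooth: float, amp: float) -> np.ndarray:
    return ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), smooth) * amp


@dataclass(frozen=True)
class Phantom:
    image: RawCTImage
    masks: dict[str, np.ndarray]


def synthesize(spec: PhantomSpec) -> Phantom:
    """Build one phantom slice plus its region masks (``body`` is the
    foreground mask background-cropping should recover)."""
    n = spec.size
    rng = np.random.default_rng(spec.seed)
    s = n / 512.0  # geometry scales with matrix size
    hu = np.full((n, n), -1000.0)  # air
    cy = n / 2 + rng.uniform(-4, 4) * s
    cx = n / 2 + rng.uniform(-4, 4) * s
    masks: dict[str, np.ndarray] = {}

    if spec.site == "head":
        body = _ellipse(n, cy, cx, 0.42 * n, 0.34 * n)
        inner = _ellipse(n, cy, cx, 0.38 * n, 0.30 * n)
        skull = body & ~inner
        hu[body] = 1100.0  # skull rim
        hu[inner] = 38.0  # brain parenchyma
        vent = _ellipse(n, cy - 0.02 * n, cx - 0.06 * n, 0.10 * n, 0.035 * n, 0.3) | _ellipse(
            n, cy - 0.02 * n, cx + 0.06 * n, 0.10 * n, 0.035 * n, -0.3
        )
        hu[vent & inner] = 8.0  # CSF-filled ventricles
        tex = _texture(rng, n, 3.0 * s, 3.0 * spec.texture_scale)
        hu[inner] += tex[inner]
        masks.update(body=body, brain=inner & ~vent, skull=skull, ventricles=vent & inner)

    elif spec.site == "chest":
        body = _ellipse(n, cy, cx, 0.36 * n, 0.45 * n)
        hu[body] = 35.0  # chest-wall soft tissue
        lung_l = _ellipse(n, cy, cx - 0.20 * n, 0.26 * n, 0.16 * n, 0.15)
        lung_r = _ellipse(n, cy, cx + 0.20 * n, 0.26 * n, 0.16 * n, -0.15)
        lungs = (lung_l | lung_r) & body
        hu[lungs] = -850.0
        # vessel-like bright texture inside the lungs
        vessels = _texture(rng, n, 1.5 * s, 1.0)
        hu[lungs] += np.clip(vessels[lungs], 0, None) * 260.0 * spec.texture_scale
        spine = _ellipse(n, cy + 0.26 * n, cx, 0.07 * n, 0.055 * n)
        hu[spine & body] = 700.0
        heart = _ellipse(n, cy + 0.04 * n, cx - 0.02 * n, 0.13 * n, 0.11 * n) & body & ~lungs
        hu[heart] = 45.0
        masks.update(body=body, lungs=lungs, spine=spine & body, wall=body & ~lungs)

    elif spec.site == "abdomen":
        body = _ellipse(n, cy, cx, 0.33 * n, 0.44 * n)
        hu[body] = 45.0
        liver = _ellipse(n, cy - 0.05 * n, cx - 0.17 * n, 0.17 * n, 0.17 * n, 0.4) & body
        hu[liver] = 60.0
        stomach = _ellipse(n, cy - 0.06 * n, cx + 0.14 * n, 0.09 * n, 0.11 * n) & body
        hu[stomach] = 20.0
        kid_l = _ellipse(n, cy + 0.14 * n, cx - 0.15 * n, 0.07 * n, 0.045 * n, 0.3) & body
        kid_r = _ellipse(n, cy + 0.14 * n, cx + 0.15 * n, 0.07 * n, 0.045 * n, -0.3) & body
        hu[kid_l | kid_r] = 35.0
        spine = _ellipse(n, cy + 0.24 * n, cx, 0.07 * n, 0.055 * n) & body
        hu[spine] = 700.0
        aorta = _ellipse(n, cy + 0.13 * n, cx + 0.01 * n, 0.03 * n, 0.03 * n) & body
        hu[aorta] = 50.0
        tex = _texture(rng, n, 2.5 * s, 6.0 * spec.texture_scale)
        soft = body & ~spine
        hu[soft] += tex[soft]
        masks.update(body=body, liver=liver, spine=spine, kidneys=kid_l | kid_r)
    else:
        raise ValueError(f"unknown site {spec.site!r}")

    stored = np.clip(hu + spec.hu_offset, 0, 65535)
    image = RawCTImage(
        pixels=stored, site=spec.site, hu_offset=spec.hu_offset, id=spec.image_id
    )
    return Phantom(image=image, masks=masks)


def make_phantom(spec: PhantomSpec) -> RawCTImage:
    """Deterministic CT-like phantom slice for the given site."""
    return synthesize(spec).image


def default_reference_specs(size: int = 512, base_seed: int = 0) -> list[PhantomSpec]:
    """The six-reference design: two phantoms per site."""
    specs = []
    for site in ("head", "chest", "abdomen"):
        for k in range(2):
            specs.append(
                PhantomSpec(site=site, size=size, seed=base_seed * 64 + hash_site(site) + k)
            )
    return specs


def hash_site(site: str) -> int:
    return {"head": 11, "chest": 23, "abdomen": 37}[site]


# ---------------------------------------------------------------------------
# Latent quality and mark simulation
# ---------------------------------------------------------------------------


def latent_quality(spec: DistortionSpec, params: ObserverModelParams) -> float:
    """Latent subjective quality of one grid cell on the 0-100 scale.

    ``Q = floor + (100 - floor) * exp(-(sn/tau_n + sb/tau_b + c*sn*sb/(tau_n*tau_b)))``
    with the interaction coefficient ``c`` zero by default.  Q(0,0) = 100 and
    Q decays strictly in each intensity with a strictly flattening rate.
    """
    z = spec.sigma_noise / params.tau_noise + spec.sigma_blur / params.tau_blur
    z += params.interaction * spec.sigma_noise * spec.sigma_blur / (
        params.tau_noise * params.tau_blur
    )
    return params.floor + (100.0 - params.floor) * float(np.exp(-z))


def _pair_iter(pairs):
    """Yield (pair_id, DistortionSpec) from ImagePairs or (id, spec) tuples."""
    for p in pairs:
        if hasattr(p, "pair_id"):
            yield p.pair_id, p.spec
        else:
            yield p


def simulate_marks(pairs, params: ObserverModelParams, seed: int = 0) -> pd.DataFrame:
    """Simulate the double-stimulus mark sheet.

    One row per (pair, observer): the observer's mark for the hidden
    reference and for the distorted image, both clipped to [0, 100], plus the
    randomized presentation order.  Observer biases are drawn once per
    observer; marks add independent noise.  Deterministic given ``seed``.
    """
    pair_list = list(_pair_iter(pairs))
    if not pair_list:
        raise ValueError("no pairs to mark")
    rng = np.random.default_rng(seed)
    bias = rng.normal(0.0, params.bias_sd, size=params.n_observers)
    rows = []
    for obs in range(params.n_observers):
        order = rng.permutation(len(pair_list))
        for idx, (pair_id, spec) in enumerate(pair_list):
            q = latent_quality(spec, params)
            mark_dist = np.clip(q + bias[obs] + rng.normal(0.0, params.mark_sd), 0.0, 100.0)
            mark_ref = np.clip(
                params.ref_mean + bias[obs] + rng.normal(0.0, params.mark_sd), 0.0, 100.0
            )
            rows.append(
                {
                    "pair_id": pair_id,
                    "observer_id": f"obs{obs}",
                    "mark_ref": float(mark_ref),
                    "mark_dist": float(mark_dist),
                    "order_index": int(order[idx]),
                    "sigma_noise": spec.sigma_noise,
                    "sigma_blur": spec.sigma_blur,
                }
            )
    return pd.DataFrame(rows)


def study_mark_sheet(
    params: ObserverModelParams,
    n_references: int = 6,
    noise_levels=NOISE_GRID,
    blur_levels=BLUR_GRID,
    seed: int = 0,
) -> pd.DataFrame:
    """Mark sheet for a full design without rendering any images (the
    observer model depends only on the distortion intensities)."""
    pairs = []
    for r in range(n_references):
        for spec in grid_specs(f"ref{r}", tuple(noise_levels), tuple(blur_levels), seed):
            pairs.append((f"ref{r}_n{spec.sigma_noise:g}_b{spec.sigma_blur:g}", spec))
    return simulate_marks(pairs, params, seed=seed)


def mean_single_distortion_curves(
    params: ObserverModelParams = ObserverModelParams(),
    n_references: int = 6,
    n_reps: int = 20,
    seed: int = 0,
    noise_levels=NOISE_GRID,
    blur_levels=BLUR_GRID,
) -> pd.DataFrame:
    """Mean subjective score per single-distortion grade, with per-grade
    decline rates.

    The observer model's mean score at each grade is estimated by averaging
    the panel means of ``n_reps`` replicate simulated studies, so the summary
    reflects the model rather than one panel's noise realization.  Returns
    one row per (kind, sigma) with columns ``mean_x`` and ``slope`` — the
    score decline per unit sigma from the previous grade (NaN at the first
    grade, which has no predecessor).  Under the default latent model both
    curves fall monotonically with strictly flattening slope.

    Note the double-stimulus construction offsets the subjective score:
    X = (100 - ref_mean) + Q up to clipping, so X, unlike Q, is not anchored
    at 100 for a pristine pair; slopes are therefore only defined between
    observed grades.
    """
    from .dscqs import subjective_table

    frames = []
    for rep in range(n_reps):
        sheet = study_mark_sheet(
            params,
            n_references=n_references,
            noise_levels=noise_levels,
            blur_levels=blur_levels,
            seed=seed + 104729 * rep,
        )
        frames.append(subjective_table(sheet))
    subj = pd.concat(frames, ignore_index=True)
    rows = []
    for kind, col, other in (
        ("noise", "sigma_noise", "sigma_blur"),
        ("blur", "sigma_blur", "sigma_noise"),
    ):
        single = subj[(subj[other] == 0) & (subj[col] > 0)]
        means = single.groupby(col)["X"].mean().sort_index()
        prev_sigma, prev_x = None, None
        for sigma, mean_x in means.items():
            slope = (
                (prev_x - mean_x) / (sigma - prev_sigma) if prev_sigma is not None else np.nan
            )
            rows.append(
                {"kind": kind, "sigma": float(sigma), "mean_x": float(mean_x), "slope": slope}
            )
            prev_sigma, prev_x = float(sigma), float(mean_x)
    return pd.DataFrame(rows)


def fit_latent_model(
    mean_scores: pd.DataFrame, params0: ObserverModelParams = ObserverModelParams()
) -> dict[str, float]:
    """Recover (floor, tau_noise, tau_blur) from per-cell mean subjective
    scores by least squares on the latent decay model.

    ``mean_scores`` needs columns ``sigma_noise``, ``sigma_blur``, ``X``.
    The known double-stimulus offset ``100 - ref_mean`` relating X to the
    latent quality is taken from ``params0``.
    """
    from scipy.optimize import least_squares

    sn = mean_scores["sigma_noise"].to_numpy(dtype=float)
    sb = mean_scores["sigma_blur"].to_numpy(dtype=float)
    x = mean_scores["X"].to_numpy(dtype=float)
    offset = 100.0 - params0.ref_mean

    def resid(theta):
        floor, tau_n, tau_b = theta
        q = floor + (100.0 - floor) * np.exp(-(sn / tau_n + sb / tau_b))
        return offset + q - x

    sol = least_squares(
        resid,
        x0=[params0.floor, params0.tau_noise, params0.tau_blur],
        bounds=([0.0, 0.1, 0.01], [99.0, 1000.0, 100.0]),
    )
    floor, tau_n, tau_b = sol.x
    return {"floor": float(floor), "tau_noise": float(tau_n), "tau_blur": float(tau_b)}


class CalibrationError(RuntimeError):
    """Target agreement unattainable under the given panel parameters."""


def calibrate_mark_noise(
    target_icc: float,
    params: ObserverModelParams = ObserverModelParams(),
    n_references: int = 6,
    n_reps: int = 20,
    seed: int = 0,
    tol: float = 0.03,
    ratings: str = "difference",
    max_iter: int = 40,
) -> tuple[float, float]:
    """Bisect ``mark_sd`` until mean simulated ICC(2,1) hits ``target_icc``.

    Agreement is measured on each replicate study's ratings matrix (per-pair
    x per-observer subjective differences by default) and averaged over
    ``n_reps`` replicates.  Returns ``(mark_sd, achieved_icc)``; raises
    :class:`CalibrationError` if the target exceeds what the noise-free
    panel can reach.
    """
    from .dscqs import icc_2_1, ratings_matrix

    if not 0 < target_icc <= 1:
        raise ValueError("target ICC must lie in (0, 1]")

    def mean_icc(mark_sd: float) -> float:
        p = replace(params, mark_sd=mark_sd)
        vals = []
        for rep in range(n_reps):
            sheet = study_mark_sheet(p, n_references=n_references, seed=seed + 7919 * rep)
            mat = ratings_matrix(sheet, kind=ratings)
            vals.append(icc_2_1(mat).icc)
        return float(np.mean(vals))

    lo, hi = 1e-3, 40.0
    icc_lo = mean_icc(lo)
    if icc_lo + tol < target_icc:
        raise CalibrationError(
            f"target ICC {target_icc} unattainable: noise-free panel reaches only {icc_lo:.3f}"
        )
    if mean_icc(hi) > target_icc:
        return hi, mean_icc(hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        achieved = mean_icc(mid)
        if abs(achieved - target_icc) <= tol:
            return mid, achieved
        if achieved > target_icc:
            lo = mid
        else:
            hi = mid
    achieved = mean_icc(0.5 * (lo + hi))
    if abs(achieved - target_icc) <= tol:
        return 0.5 * (lo + hi), achieved
    raise CalibrationError(
        f"bisection did not reach target {target_icc} (last achieved {achieved:.3f})"
    )
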