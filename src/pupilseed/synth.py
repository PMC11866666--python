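"""Synthetic cohorts of coupled pupil traces and BOLD datasets.

Every downstream stage of the package is testable without real data:
this module generates, with known ground truth,

- a slow latent arousal process (Ornstein-Uhlenbeck, so its power is
  concentrated in the 0.008-0.09 Hz analysis band),
- camera-rate pupil traces of that process with measurement noise and
  blink-like runs of missing / low-confidence frames (emulating the
  per-frame output of a video pupil segmenter),
- 4D BOLD datasets in which planted voxel clusters are coupled to the
  HRF-convolved latent signal or to its first derivative, all other
  voxels being noise, plus random-walk motion parameters and slow
  tissue nuisance signals,
- a two-group cohort (younger / older, older defined as age > 57 years)
  with phenotypes, optional attenuation of derivative coupling in the
  older group, and covariates drawn with a specified correlation to
  each subject's coupling strength.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .boldprep import BOLDDataset, write_motion_tsv
from .pupil import PupilTrace, canonical_hrf, default_volume_times, write_trace_tsv

__all__ = [
    "ArousalParams",
    "PlantSpec",
    "CohortSpec",
    "Cohort",
    "SubjectData",
    "simulate_arousal",
    "simulate_pupil_trace",
    "simulate_bold_subject",
    "simulate_cohort",
    "write_cohort",
    "block_plant",
]

# Group phenotype distributions the generator emulates: per-measure
# (younger mean, younger sd, older mean, older sd); None = not collected
# in that group.
SCORE_DISTRIBUTIONS = {
    "MoCA": (28.6, 1.3, 26.4, 2.6),
    "FCSRT_free_recall": (40.4, 4.6, 35.9, 3.4),
    "RCFT_immediate_free_recall": (26.2, 3.7, 19.1, 7.3),
    "RCFT_delayed_free_recall": (25.3, 4.0, 16.8, 8.3),
    "RCFT_recognition": (21.8, 1.0, 19.9, 1.7),
    "RCFT_copy_accuracy": (33.2, 3.2, 32.2, 2.9),
    "JoLO": (25.4, 2.9, 24.2, 4.2),
    "FAS": (45.9, 7.8, 43.2, 10.7),
    "Animal_Fluency": (24.4, 4.4, 22.8, 3.8),
    "TMTA": (25.6, 9.6, 35.8, 13.4),
    "TMTB": (52.4, 11.2, 76.4, 30.7),
}
CSF_DISTRIBUTIONS = {
    "abeta42": (535.5, 145.2),
    "t_tau": (58.6, 28.9),
    "p_tau": (29.7, 13.9),
}
AGE_DISTRIBUTIONS = {"younger": (30.6, 10.6), "older": (66.0, 5.7)}
MALE_FRACTION = {"younger": 15 / 37, "older": 7 / 39}
EDUCATION_DISTRIBUTIONS = {"younger": (16.8, 1.3), "older": (16.4, 2.0)}
AGE_CUTOFF = 57.0


@dataclass(frozen=True)
class ArousalParams:
    """Latent arousal process: stationary mean and SD (a.u.),
    autocorrelation time tau (s), simulation step dt (s)."""

    mean_level: float = 4.0
    sd: float = 0.4
    tau: float = 10.0
    dt: float = 1.0 / 60.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")


@dataclass(frozen=True)
class PlantSpec:
    """A voxel set coupled to the seed signal.

    ``coupling_beta`` is the standardized effect of the (unit-variance)
    regressor on the voxel signal; ``coupled_to`` selects the
    HRF-convolved diameter or its first derivative;
    ``group_attenuation`` in [0, 1] multiplies the coupling in the
    older group (derivative coupling weakening with age)."""

    voxels: tuple
    coupling_beta: float = 0.5
    coupled_to: str = "diameter"
    group_attenuation: float = 1.0

    def __post_init__(self) -> None:
        if self.coupled_to not in ("diameter", "derivative"):
            raise ValueError("coupled_to must be 'diameter' or 'derivative'")
        if not (0 <= self.group_attenuation <= 1):
            raise ValueError("group_attenuation must be in [0, 1]")

    def voxel_array(self) -> np.ndarray:
        return np.asarray(self.voxels, dtype=int).reshape(-1, 3)


def block_plant(
    corner: tuple, shape: tuple, **kwargs
) -> PlantSpec:
    """Convenience: a rectangular block of voxels as a plant."""
    idx = np.stack(
        np.meshgrid(
            *[np.arange(c, c + s) for c, s in zip(corner, shape)], indexing="ij"
        ),
        axis=-1,
    ).reshape(-1, 3)
    return PlantSpec(voxels=tuple(map(tuple, idx)), **kwargs)


@dataclass(frozen=True)
class CohortSpec:
    """Study-scale defaults: 37 younger + 39 older subjects, 320 volumes
    at TR = 1.89 s, 60 Hz camera.

    ``coupling_sd`` is the relative between-subject spread of planted
    couplings (so covariates can correlate with subject coupling);
    ``noise_sd`` is BOLD voxel noise, ``pupil_noise_sd`` camera
    measurement noise; ``missing_frac`` is the expected fraction of
    blink-like missing frames; ``covariate_effects`` maps phenotype
    column names to their correlation with subject coupling strength."""

    n_young: int = 37
    n_old: int = 39
    grid_shape: tuple = (24, 24, 12)
    n_volumes: int = 320
    tr: float = 1.89
    camera_rate: float = 60.0
    voxel_size: float = 1.5
    plants: tuple = ()
    noise_sd: float = 1.0
    pupil_noise_sd: float = 0.05
    missing_frac: float = 0.05
    coupling_sd: float = 0.30
    covariate_effects: tuple = ()  # ((name, rho), ...)
    arousal: ArousalParams = field(default_factory=ArousalParams)
    blink_mode: str = "runs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        if self.tr <= 0 or self.camera_rate <= 0:
            raise ValueError("tr and camera_rate must be positive")
        if not (0 <= self.missing_frac < 1):
            raise ValueError("missing_frac must be in [0, 1)")
        shape = np.asarray(self.grid_shape)
        for p in self.plants:
            vox = p.voxel_array()
            if np.any(vox < 0) or np.any(vox >= shape):
                raise ValueError("plant voxels fall outside the grid")

    @property
    def n_subjects(self) -> int:
        return self.n_young + self.n_old

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size
        return a

    def volume_times(self) -> np.ndarray:
        return default_volume_times(self.n_volumes, self.tr)


# ---------------------------------------------------------------------------
# elementary simulators


def simulate_arousal(
    params: ArousalParams, duration: float, seed=None
) -> np.ndarray:
    """Exact-discretisation Ornstein-Uhlenbeck series of length
    floor(duration/dt) + 1 with stationary mean ``mean_level`` and
    stationary SD ``sd``; deterministic given the seed."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration < params.dt:
        raise ValueError("duration must be at least one step dt")
    n = int(np.floor(duration / params.dt)) + 1
    rng = np.random.default_rng(seed)
    a = np.exp(-params.dt / params.tau)
    innov = rng.standard_normal(n)
    innov[0] *= params.sd  # stationary start
    innov[1:] *= params.sd * np.sqrt(1.0 - a * a)
    y = lfilter([1.0], [1.0, -a], innov)
    return params.mean_level + y


def _missing_mask(n: int, frac: float, mode: str, rng, mean_run: float = 10.0):
    if frac == 0:
        return np.zeros(n, dtype=bool)
    if mode == "iid":
        return rng.random(n) < frac
    if mode == "runs":
        # blink-like: geometric run lengths (mean ``mean_run`` frames),
        # run starts at rate frac/mean_run so the expected missing
        # fraction is ``frac``
        starts = rng.random(n) < frac / mean_run
        miss = np.zeros(n, dtype=bool)
        for s in np.flatnonzero(starts):
            run = rng.geometric(1.0 / mean_run)
            miss[s : s + run] = True
        return miss
    raise ValueError(f"unknown blink mode {mode!r}")


def simulate_pupil_trace(
    latent: np.ndarray,
    camera_rate: float,
    noise_sd: float = 0.05,
    missing_frac: float = 0.05,
    seed=None,
    blink_mode: str = "runs",
) -> PupilTrace:
    """Camera-rate segmenter-style trace of a latent series: diameter =
    latent + iid noise; an expected ``missing_frac`` of frames flagged
    missing with confidence below 0.9, the rest with confidence at or
    above 0.9; frames uniformly spaced at 1/camera_rate."""
    latent = np.asarray(latent, dtype=float)
    if latent.size == 0:
        raise ValueError("latent series is empty")
    if not (0 <= missing_frac < 1):
        raise ValueError("missing_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = latent.size
    time = np.arange(n) / camera_rate
    diameter = latent + noise_sd * rng.standard_normal(n)
    missing = _missing_mask(n, missing_frac, blink_mode, rng)
    confidence = rng.uniform(0.90, 1.0, size=n)
    confidence[missing] = rng.uniform(0.0, 0.89, size=int(missing.sum()))
    return PupilTrace(time=time, diameter=diameter, confidence=confidence,
                      missing=missing)


def _regressors_at_volumes(latent: np.ndarray, spec: CohortSpec):
    """Unit-variance HRF-convolved latent and its first derivative,
    sampled at the volume acquisition times (ground-truth regressors
    the analysis chain should recover)."""
    dt = 1.0 / spec.camera_rate
    kernel = canonical_hrf(dt=dt)
    # steady-state pre-history (same convention as the analysis chain)
    padded = np.concatenate([np.full(kernel.size - 1, latent[0]), latent])
    conv = np.convolve(padded, kernel, mode="full")[
        kernel.size - 1 : kernel.size - 1 + latent.size
    ]
    t = np.arange(latent.size) * dt
    vt = spec.volume_times()
    diam = np.interp(vt, t, conv)
    deriv_full = np.gradient(conv, dt)
    deriv = np.interp(vt, t, deriv_full)

    def standardize(v):
        s = v.std()
        return (v - v.mean()) / s if s > 0 else v - v.mean()

    return standardize(diam), standardize(deriv)


def simulate_bold_subject(
    latent: np.ndarray,
    spec: CohortSpec,
    subject_couplings: dict | None = None,
    seed=None,
) -> tuple[BOLDDataset, pd.DataFrame]:
    """A subject's 4D BOLD dataset plus tissue nuisance signals.

    Planted voxel series are beta * (standardized HRF-convolved latent
    or its derivative, per the plant's ``coupled_to``) + Gaussian noise
    of SD ``spec.noise_sd``; every other voxel is pure noise.  Motion
    parameters are six independent small random walks; white-matter and
    CSF nuisance columns are slow autocorrelated signals.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    diam, deriv = _regressors_at_volumes(latent, spec)
    T = spec.n_volumes
    shape = spec.grid_shape
    data = spec.noise_sd * rng.standard_normal((*shape, T))
    betas = {}
    for pi, plant in enumerate(spec.plants):
        beta = plant.coupling_beta
        if subject_couplings is not None and pi in subject_couplings:
            beta = subject_couplings[pi]
        reg = diam if plant.coupled_to == "diameter" else deriv
        vox = plant.voxel_array()
        data[vox[:, 0], vox[:, 1], vox[:, 2], :] += beta * reg
        betas[pi] = beta
    motion = np.cumsum(
        rng.standard_normal((T, 6)) * np.array([0.02] * 3 + [0.0005] * 3),
        axis=0,
    )
    tau_vols = 20.0 / spec.tr
    a = np.exp(-1.0 / tau_vols)
    wm = lfilter([1.0], [1.0, -a], rng.standard_normal(T) * np.sqrt(1 - a * a))
    csf = lfilter([1.0], [1.0, -a], rng.standard_normal(T) * np.sqrt(1 - a * a))
    confounds = pd.DataFrame({"white_matter": wm, "csf": csf})
    bold = BOLDDataset(
        data=data,
        mask=np.ones(shape, dtype=bool),
        tr=spec.tr,
        motion=motion,
        affine=spec.affine,
        meta={"planted_betas": betas},
    )
    return bold, confounds


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SubjectData:
    """One subject's raw inputs as the study would provide them."""

    id: str
    trace: PupilTrace
    bold: BOLDDataset
    confounds: pd.DataFrame


@dataclass
class Cohort:
    """A simulated cohort: phenotypes, lazy per-subject raw data, and
    the ground-truth record needed for recovery tests."""

    spec: CohortSpec
    phenotype: pd.DataFrame
    truth: dict
    _subject_seeds: list = field(default_factory=list, repr=False)

    @property
    def n_subjects(self) -> int:
        return self.spec.n_subjects

    def subject(self, i: int) -> SubjectData:
        """Generate subject ``i`` deterministically from its spawned
        seed; repeated calls are bit-identical."""
        trace_seed, bold_seed, latent_seed = self._subject_seeds[i]
        latent = simulate_arousal(
            self.spec.arousal, self.spec.duration, seed=latent_seed
        )
        trace = simulate_pupil_trace(
            latent,
            self.spec.camera_rate,
            noise_sd=self.spec.pupil_noise_sd,
            missing_frac=self.spec.missing_frac,
            seed=trace_seed,
            blink_mode=self.spec.blink_mode,
        )
        couplings = {
            int(pi): float(b)
            for pi, b in self.truth["subject_betas"][i].items()
        }
        bold, confounds = simulate_bold_subject(
            latent, self.spec, subject_couplings=couplings, seed=bold_seed
        )
        return SubjectData(
            id=self.phenotype["id"].iloc[i], trace=trace, bold=bold,
            confounds=confounds,
        )

    def iter_subjects(self):
        for i in range(self.n_subjects):
            yield self.subject(i)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.normal(mean, sd, size=int(need.sum()))
        ok = (draw > lo) & (draw < hi)
        idx = np.flatnonzero(need)[ok]
        out[idx] = draw[ok]
        need[idx] = False
    return out


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate phenotypes, per-subject coupling strengths and the
    ground-truth record for a full two-group cohort.

    Older subjects' derivative-coupled betas are multiplied by the
    plant's ``group_attenuation``; each covariate named in
    ``covariate_effects`` is drawn bivariate-normally with the given
    correlation to the subject's latent coupling factor.  Raw traces and
    BOLD volumes are generated lazily per subject (see
    :meth:`Cohort.subject`).
    """
    root = np.random.SeedSequence(spec.seed)
    pheno_seed, *subj_seqs = root.spawn(1 + spec.n_subjects)
    rng = np.random.default_rng(pheno_seed)
    n = spec.n_subjects
    groups = ["younger"] * spec.n_young + ["older"] * spec.n_old

    ages = np.concatenate(
        [
            _truncated_normal(rng, *AGE_DISTRIBUTIONS["younger"], 18.0, AGE_CUTOFF,
                              spec.n_young),
            _truncated_normal(rng, *AGE_DISTRIBUTIONS["older"], AGE_CUTOFF, 95.0,
                              spec.n_old),
        ]
    )
    sex = np.concatenate(
        [
            np.where(rng.random(spec.n_young) < MALE_FRACTION["younger"], "M", "F"),
            np.where(rng.random(spec.n_old) < MALE_FRACTION["older"], "M", "F"),
        ]
    )
    edu = np.concatenate(
        [
            rng.normal(*EDUCATION_DISTRIBUTIONS["younger"], spec.n_young),
            rng.normal(*EDUCATION_DISTRIBUTIONS["older"], spec.n_old),
        ]
    )
    pheno = pd.DataFrame(
        {
            "id": [f"S{i + 1:03d}" for i in range(n)],
            "group": groups,
            "age_years": np.round(ages, 1),
            "sex": sex,
            "education_years": np.round(edu, 1),
        }
    )
    for name, (ym, ys, om, osd) in SCORE_DISTRIBUTIONS.items():
        pheno[name] = np.round(
            np.concatenate(
                [rng.normal(ym, ys, spec.n_young), rng.normal(om, osd, spec.n_old)]
            ),
            1,
        )
    old_mask = np.array([g == "older" for g in groups])
    for name, (m, s) in CSF_DISTRIBUTIONS.items():
        col = np.full(n, np.nan)
        col[old_mask] = np.maximum(rng.normal(m, s, spec.n_old), 1.0)
        pheno[name] = np.round(col, 1)
    pheno["t_tau_abeta_ratio"] = np.round(pheno["t_tau"] / pheno["abeta42"], 4)

    # per-subject coupling factor and planted betas
    u = rng.standard_normal(n)  # latent coupling factor, N(0, 1)
    subject_betas = []
    for i in range(n):
        betas = {}
        for pi, plant in enumerate(spec.plants):
            beta = plant.coupling_beta * (1.0 + spec.coupling_sd * u[i])
            if old_mask[i] and plant.coupled_to == "derivative":
                beta *= plant.group_attenuation
            betas[pi] = max(float(beta), 0.0)
        subject_betas.append(betas)

    # covariates tied to the coupling factor
    cov_effects = dict(spec.covariate_effects)
    for name, rho in cov_effects.items():
        base = pheno[name].to_numpy(dtype=float)
        obs = ~np.isnan(base)
        m, s = np.nanmean(base), np.nanstd(base)
        if s == 0 or not np.isfinite(s):
            m, s = 0.0, 1.0
        noise = rng.standard_normal(n)
        latent_cov = rho * u + np.sqrt(max(1.0 - rho ** 2, 0.0)) * noise
        new = m + s * latent_cov
        new[~obs] = np.nan
        pheno[name] = np.round(new, 2)

    truth = {
        "plants": [
            {
                "voxels": [list(map(int, v)) for v in p.voxel_array()],
                "coupling_beta": p.coupling_beta,
                "coupled_to": p.coupled_to,
                "group_attenuation": p.group_attenuation,
            }
            for p in spec.plants
        ],
        "subject_betas": [
            {str(k): v for k, v in b.items()} for b in subject_betas
        ],
        "coupling_factor": u.tolist(),
        "covariate_effects": cov_effects,
        "seed": spec.seed,
    }
    # normalise subject_betas keys to ints for in-memory use
    truth["subject_betas"] = [
        {int(k): v for k, v in b.items()} for b in truth["subject_betas"]
    ]
    subject_seeds = [tuple(s.spawn(3)) for s in subj_seqs]
    return Cohort(
        spec=spec, phenotype=pheno, truth=truth, _subject_seeds=subject_seeds
    )


def plant_mask(spec: CohortSpec) -> np.ndarray:
    """Integer volume marking each plant's voxels with its 1-based
    index (ground-truth closure: exactly the planted voxels)."""
    vol = np.zeros(spec.grid_shape, dtype=np.int16)
    for pi, plant in enumerate(spec.plants):
        vox = plant.voxel_array()
        vol[vox[:, 0], vox[:, 1], vox[:, 2]] = pi + 1
    return vol


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort to disk: per-subject BOLD + mask NIfTI, trace
    and motion TSVs, phenotype CSV, plant-truth NIfTI, truth JSON."""
    import os

    import nibabel as nib

    os.makedirs(outdir, exist_ok=True)
    cohort.phenotype.to_csv(os.path.join(outdir, "phenotype.csv"), index=False)
    spec = cohort.spec
    nib.save(
        nib.Nifti1Image(plant_mask(spec), spec.affine),
        os.path.join(outdir, "plant_truth.nii.gz"),
    )
    truth = dict(cohort.truth)
    truth["subject_betas"] = [
        {str(k): v for k, v in b.items()} for b in truth["subject_betas"]
    ]
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
    with open(os.path.join(outdir, "spec.json"), "w") as fh:
        json.dump(
            {
                **{
                    k: v
                    for k, v in asdict(spec).items()
                    if k not in ("plants", "arousal", "covariate_effects")
                },
                "n_plants": len(spec.plants),
            },
            fh,
            indent=2,
        )
    for i, subj in enumerate(cohort.iter_subjects()):
        sid = subj.id
        nib.save(subj.bold.to_nifti(), os.path.join(outdir, f"{sid}_bold.nii.gz"))
        nib.save(
            nib.Nifti1Image(subj.bold.mask.astype(np.int16), spec.affine),
            os.path.join(outdir, f"{sid}_mask.nii.gz"),
        )
        write_trace_tsv(subj.trace, os.path.join(outdir, f"{sid}_pupil.tsv"))
        write_motion_tsv(subj.bold.motion, os.path.join(outdir, f"{sid}_motion.tsv"))
        subj.confounds.to_csv(
            os.path.join(outdir, f"{sid}_confounds.tsv"), sep="\t", index=False
        )
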