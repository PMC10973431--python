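"""Ground-truth phantoms: capnograph traces, IC mixing matrices, BOLD volumes.

The generator emulates a CO2-inhalation block paradigm: end-tidal CO2
alternates between a normocapnic baseline and a hypercapnic plateau, the
capnograph records breath-by-breath oscillations whose expiratory peaks
track that designed envelope, and every voxel's BOLD timecourse follows

    Y_v(t) = b0_v * [1 + (CVR_v / 100) * (etCO2(t - g - d_v) - baseline)] + noise

where g is the global acquisition lag (the gas sampling line), d_v the
voxel's local arrival delay, and the noise is white Gaussian calibrated to
a target temporal SNR.  Block transitions are smoothed with a Gaussian ramp
(sigma 5 s) because alveolar CO2 follows the inhaled step with a lung
washout ramp rather than instantaneously.  The mixing matrix contains one
component proportional to the (globally shifted) etCO2 — deliberately
mislabelled as noise to exercise the reclassification step — plus
drift/spike/white-noise components that genuinely are noise.

Everything is driven by one seeded generator: identical seeds give
bitwise-identical phantoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

from .denoise import ICDecomposition
from .errors import ValidationError
from .physio import CapnoTrace
from .volume import BoldVolume


@dataclass
class PhantomSpec:
    """Design parameters of a synthetic CVR acquisition.

    Defaults describe a typical block-design CO2 inhalation run: a 6-minute
    scan (180 frames, TR 2 s) with 60-s alternating blocks of 38 and
    45 mmHg etCO2, breathing at 0.25 Hz recorded at 10 Hz, a 10-s gas
    sampling-line lag, and voxel tSNR of 50.
    """

    shape: tuple[int, int, int] = (10, 10, 10)
    n_frames: int = 180
    tr: float = 2.0
    # etCO2 design
    baseline_mmhg: float = 38.0
    hypercapnia_mmhg: float = 45.0
    block_s: float = 60.0
    ramp_sigma_s: float = 5.0
    # capnograph
    breathing_hz: float = 0.25
    capno_fs: float = 10.0
    capno_dip_mmhg: float = 2.0
    peak_jitter_mmhg: float = 0.0
    capno_units: str = "mmHg"
    capno_start_s: float = 0.0
    capno_duration_s: float | None = None
    # hemodynamics
    global_delay_s: float = 10.0
    cvr_true: np.ndarray | None = None  # %BOLD/mmHg; default uniform 0.3
    delay_true: np.ndarray | None = None  # local delays in s; default 0
    beta0_range: tuple[float, float] = (800.0, 1200.0)
    tsnr: float = 50.0
    # confound components
    noise_ic_kinds: tuple[str, ...] = ("drift", "spikes", "white", "white", "white")
    noise_ic_sd: float = 10.0
    voxel_size_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tsnr > 0:
            raise ValidationError("tSNR must be positive (use np.inf for noiseless)")
        if self.capno_duration_s is None:
            self.capno_duration_s = self.n_frames * self.tr
        self.cvr_true = self._as_map(self.cvr_true, 0.3)
        self.delay_true = self._as_map(self.delay_true, 0.0)

    def _as_map(self, value, default: float) -> np.ndarray:
        if value is None:
            return np.full(self.shape, default, dtype=float)
        arr = np.asarray(value, dtype=float)
        if arr.shape != tuple(self.shape):
            raise ValidationError(f"truth map shape {arr.shape} != grid {self.shape}")
        return arr

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    def etco2_design(self, t: np.ndarray) -> np.ndarray:
        """Designed etCO2 envelope, baseline for t < 0, smooth block edges."""
        t = np.asarray(t, dtype=float)
        amp = self.hypercapnia_mmhg - self.baseline_mmhg
        out = np.full(t.shape, self.baseline_mmhg)
        t_max = float(t.max(initial=0.0)) + 4 * self.ramp_sigma_s
        n_cycles = int(t_max // (2 * self.block_s)) + 1

        def smooth_step(x):  # Gaussian-filtered unit step
            return 0.5 * (1 + erf(x / (np.sqrt(2) * self.ramp_sigma_s)))

        for k in range(n_cycles):
            rise = (2 * k + 1) * self.block_s
            fall = (2 * k + 2) * self.block_s
            out = out + amp * (smooth_step(t - rise) - smooth_step(t - fall))
        return out


def two_compartment_truth(
    shape: tuple[int, int, int] = (10, 10, 10),
    cvr_gm: float = 0.5,
    cvr_wm: float = 0.25,
    wm_delay_s: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grey/white-matter-style split along x: returns (cvr, delay, gm_mask).

    Mirrors the physiology that grey matter reacts more strongly and is
    reached by the CO2 bolus earlier than white matter.
    """
    cvr = np.full(shape, cvr_wm, dtype=float)
    delay = np.full(shape, wm_delay_s, dtype=float)
    gm = np.zeros(shape, dtype=bool)
    gm[: shape[0] // 2] = True
    cvr[gm] = cvr_gm
    delay[gm] = 0.0
    return cvr, delay, gm


def random_truth(
    shape: tuple[int, int, int],
    rng: np.random.Generator,
    cvr_range: tuple[float, float] = (0.1, 0.6),
    delay_range: tuple[float, float] = (-4.0, 8.0),
    delay_step: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel CVR ~ U(cvr_range) and delays drawn on the search grid."""
    cvr = rng.uniform(*cvr_range, size=shape)
    lo = int(round(delay_range[0] / delay_step))
    hi = int(round(delay_range[1] / delay_step))
    delay = rng.integers(lo, hi + 1, size=shape) * delay_step
    return cvr, delay.astype(float)


def make_capno(spec: PhantomSpec) -> CapnoTrace:
    """Synthesize the raw capnograph recording for a phantom.

    The trace oscillates between an inspiratory dip and the designed etCO2
    envelope once per breath, with optional per-breath Gaussian jitter on
    the expiratory plateau.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    n = int(round(spec.capno_duration_s * spec.capno_fs)) + 1
    t = spec.capno_start_s + np.arange(n) / spec.capno_fs
    env = spec.etco2_design(t)
    if spec.peak_jitter_mmhg > 0:
        breath = np.floor((t - t[0]) * spec.breathing_hz).astype(int)
        jitter = rng.normal(0.0, spec.peak_jitter_mmhg, size=breath.max() + 1)
        env = env + jitter[breath]
    # sharp-peaked breathing waveform: 1 at end-expiration, 0 at inspiration
    w = (0.5 * (1 - np.cos(2 * np.pi * spec.breathing_hz * (t - t[0])))) ** 4
    samples = spec.capno_dip_mmhg + (env - spec.capno_dip_mmhg) * w
    if spec.capno_units == "percent":
        samples = samples * (100.0 / 760.0)
    return CapnoTrace(
        samples=samples,
        sampling_frequency=spec.capno_fs,
        start_time=spec.capno_start_s,
        units=spec.capno_units,
    )


def _noise_ic_timecourse(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    t = np.linspace(-1, 1, n)
    if kind == "drift":
        return t + 0.5 * rng.standard_normal() * (t**2 - 1 / 3)
    if kind == "spikes":
        x = np.zeros(n)
        idx = rng.choice(n, size=max(2, n // 30), replace=False)
        x[idx] = rng.choice([-1.0, 1.0], size=idx.size) * rng.uniform(3, 6, size=idx.size)
        return x + 0.05 * rng.standard_normal(n)
    if kind == "white":
        return rng.standard_normal(n)
    raise ValidationError(f"unknown noise IC kind {kind!r}")


def make_bold(
    spec: PhantomSpec,
) -> tuple[BoldVolume, ICDecomposition, dict]:
    """Build the 4D BOLD phantom, its IC mixing matrix, and the ground truth.

    Returns
    -------
    bold : BoldVolume
    decomp : ICDecomposition
        Component 0 is the z-scored etCO2 regressor at the global lag,
        mislabelled noise; the remaining components are genuine confounds
        (also labelled noise) whose spatial loadings are added to the data.
    truth : dict
        ``cvr``, ``delay`` (local, s), ``total_delay`` (g + d_v, s),
        ``global_delay``, ``beta0``, ``baseline`` and the noiseless global
        signal.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2]))
    t = spec.frame_times
    nx, ny, nz = spec.shape
    n_vox = nx * ny * nz

    cvr = spec.cvr_true.reshape(-1)
    local_delay = spec.delay_true.reshape(-1)
    beta0 = rng.uniform(*spec.beta0_range, size=n_vox)

    total_delay = spec.global_delay_s + local_delay
    Y = np.empty((spec.n_frames, n_vox))
    for d in np.unique(total_delay):
        e = spec.etco2_design(t - d)
        sel = total_delay == d
        Y[:, sel] = beta0[sel] * (
            1 + (cvr[sel] / 100.0) * (e[:, None] - spec.baseline_mmhg)
        )

    # Confound components with random spatial loadings.  Their timecourses
    # are orthogonalized against the intercept and every CO2 regressor the
    # phantom contains, so that non-aggressive denoising removes exactly the
    # injected confound and the noiseless phantom stays an exact fixed point
    # of the analysis (generator/model consistency).
    kinds = spec.noise_ic_kinds
    if kinds:
        noise_tc = np.column_stack(
            [_noise_ic_timecourse(k, spec.n_frames, rng) for k in kinds]
        )
        co2_span = np.column_stack(
            [np.ones(spec.n_frames)]
            + [spec.etco2_design(t - d) for d in np.unique(total_delay)]
            + [spec.etco2_design(t - spec.global_delay_s)]
        )
        q, _ = np.linalg.qr(co2_span)
        noise_tc = noise_tc - q @ (q.T @ noise_tc)
        loadings = rng.normal(0.0, spec.noise_ic_sd, size=(len(kinds), n_vox))
        Y = Y + noise_tc @ loadings
    else:
        noise_tc = np.empty((spec.n_frames, 0))

    if np.isfinite(spec.tsnr):
        Y = Y + rng.normal(0.0, 1.0, size=Y.shape) * (beta0 / spec.tsnr)

    def zscore(x):
        return (x - x.mean()) / x.std()

    co2_ic = zscore(spec.etco2_design(t - spec.global_delay_s))
    mixing = np.column_stack([co2_ic] + [zscore(noise_tc[:, i]) for i in range(len(kinds))])
    decomp = ICDecomposition(
        mixing=mixing,
        noise_indices=frozenset(range(len(kinds) + 1)),  # CO2 IC mislabelled
    )

    data = Y.T.reshape(nx, ny, nz, spec.n_frames)
    mask = np.ones(spec.shape, dtype=bool)
    bold = BoldVolume(data=data, affine=spec.affine, mask=mask, tr=spec.tr)
    truth = {
        "cvr": spec.cvr_true.copy(),
        "delay": spec.delay_true.copy(),
        "total_delay": total_delay.reshape(spec.shape),
        "global_delay": spec.global_delay_s,
        "beta0": beta0.reshape(spec.shape),
        "baseline": spec.baseline_mmhg,
    }
    return bold, decomp, truth


def make_bids_tree(
    spec: PhantomSpec,
    out_dir: str | Path,
    subject: str = "01",
    task: str = "gas",
    space: str = "MNI152NLin6Asym",
) -> dict:
    """Write a synthetic raw-BIDS + fMRIPrep-style derivatives tree.

    Produces everything ``bids_io.discover_inputs`` needs: the gzipped
    physio TSV with its JSON sidecar under ``<out>/bids`` and the preproc
    BOLD, brain mask, MELODIC mixing TSV and (1-based) AROMA noise-IC CSV
    under ``<out>/fmriprep``.  Returns the two roots plus the ground truth.
    """
    out_dir = Path(out_dir)
    bids_root = out_dir / "bids"
    fprep_root = out_dir / "fmriprep"

    trace = make_capno(spec)
    bold, decomp, truth = make_bold(spec)

    func_raw = bids_root / f"sub-{subject}" / "func"
    func_raw.mkdir(parents=True, exist_ok=True)
    (bids_root / "dataset_description.json").write_text(
        json.dumps({"Name": "cvrkit synthetic phantom", "BIDSVersion": "1.8.0"}, indent=2)
    )
    stem = f"sub-{subject}_task-{task}"
    pd.DataFrame({"co2": trace.samples}).to_csv(
        func_raw / f"{stem}_physio.tsv.gz",
        sep="\t", header=False, index=False, compression="gzip",
    )
    units = "%" if spec.capno_units == "percent" else "mmHg"
    (func_raw / f"{stem}_physio.json").write_text(
        json.dumps(
            {
                "SamplingFrequency": trace.sampling_frequency,
                "StartTime": trace.start_time,
                "Columns": ["co2"],
                "co2": {"Units": units},
            },
            indent=2,
        )
    )

    func_prep = fprep_root / f"sub-{subject}" / "func"
    func_prep.mkdir(parents=True, exist_ok=True)
    (fprep_root / "dataset_description.json").write_text(
        json.dumps(
            {
                "Name": "synthetic fMRIPrep-style derivatives",
                "BIDSVersion": "1.8.0",
                "DatasetType": "derivative",
            },
            indent=2,
        )
    )
    import nibabel as nib

    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    img.header.set_zooms((*[spec.voxel_size_mm] * 3, spec.tr))
    nib.save(img, func_prep / f"{stem}_space-{space}_desc-preproc_bold.nii.gz")
    nib.save(
        nib.Nifti1Image(bold.mask.astype(np.uint8), bold.affine),
        func_prep / f"{stem}_space-{space}_desc-brain_mask.nii.gz",
    )
    np.savetxt(func_prep / f"{stem}_desc-MELODIC_mixing.tsv", decomp.mixing, delimiter="\t")
    (func_prep / f"{stem}_AROMAnoiseICs.csv").write_text(
        ",".join(str(i + 1) for i in sorted(decomp.noise_indices))  # 1-based convention
    )
    return {
        "bids_dir": bids_root,
        "fmriprep_dir": fprep_root,
        "subject": subject,
        "task": task,
        "space": space,
        "truth": truth,
        "spec": spec,
    }
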