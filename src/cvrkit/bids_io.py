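"""BIDS raw + fMRIPrep-derivative input discovery and BIDS-derivatives output.

Inputs are resolved with readable, exhaustive error messages: one pass over
the dataset reports *every* missing piece.  Outputs (CVR and delay maps,
etCO2 timecourse, IC reclassification table) follow BIDS-derivatives naming
with the suffix vocabulary documented in ``dataset_description.json``; the
output grid and affine are always those of the input preprocessed BOLD —
this tool never resamples.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InputDiscoveryError, ValidationError
from .physio import CapnoTrace, EtCO2Series
from .volume import BoldVolume

PIPELINE_NAME = "cvrkit"

# BIDS entity grammar: key-value pairs separated by underscores, then suffix.
_ENTITY_ORDER = ("sub", "ses", "task", "run", "space", "desc")
_BIDS_NAME_RE = re.compile(
    r"^(?P<entities>(?:[a-zA-Z0-9]+-[a-zA-Z0-9]+)(?:_[a-zA-Z0-9]+-[a-zA-Z0-9]+)*)"
    r"_(?P<suffix>[a-zA-Z0-9]+)"
    r"(?P<ext>(?:\.[a-zA-Z0-9]+)+)$"
)


def parse_bids_name(filename: str | Path) -> dict:
    """Split a BIDS filename into entities, suffix and extension.

    Raises ``ValidationError`` if the name does not follow the
    ``key-value[_key-value...]_suffix.ext`` grammar.
    """
    name = Path(filename).name
    m = _BIDS_NAME_RE.match(name)
    if m is None:
        raise ValidationError(f"filename {name!r} does not follow BIDS entity grammar")
    entities = {}
    for pair in m.group("entities").split("_"):
        key, value = pair.split("-", 1)
        entities[key] = value
    return {"entities": entities, "suffix": m.group("suffix"), "ext": m.group("ext")}


def build_bids_name(entities: dict, suffix: str, ext: str) -> str:
    """Assemble a BIDS filename with entities in canonical order."""
    parts = [f"{k}-{entities[k]}" for k in _ENTITY_ORDER if k in entities]
    extra = [f"{k}-{v}" for k, v in entities.items() if k not in _ENTITY_ORDER]
    return "_".join(parts + extra) + f"_{suffix}{ext}"


@dataclass
class ParticipantContext:
    """Resolved input paths and acquisition parameters for one participant."""

    subject: str
    task: str
    space: str
    bold_path: Path
    mask_path: Path
    mixing_path: Path
    noise_ics_path: Path
    physio_tsv: Path
    physio_json: Path
    tr: float


def _find_unique(directory: Path, pattern: str, what: str, problems: list[str]):
    hits = sorted(directory.glob(pattern)) if directory.is_dir() else []
    if len(hits) == 1:
        return hits[0]
    if not hits:
        problems.append(what)
    else:
        problems.append(
            f"ambiguous match for {pattern!r}: " + ", ".join(h.name for h in hits)
        )
    return None


def discover_inputs(
    bids_dir: str | Path,
    fmriprep_dir: str | Path,
    subject: str,
    task: str = "gas",
    space: str | None = None,
) -> ParticipantContext:
    """Resolve all required inputs for one participant, or fail readably.

    Checks the raw BIDS tree for the physio recording (TSV.GZ + JSON
    sidecar) and the fMRIPrep derivatives for the preprocessed BOLD, brain
    mask, MELODIC mixing matrix and AROMA noise-IC list.  Every missing or
    ambiguous piece is listed in a single ``InputDiscoveryError``.
    """
    bids_dir = Path(bids_dir)
    fmriprep_dir = Path(fmriprep_dir)
    problems: list[str] = []
    for d, label in ((bids_dir, "BIDS directory"), (fmriprep_dir, "fMRIPrep directory")):
        if not d.is_dir():
            problems.append(f"{label} not found: {d}")
    if problems:
        raise InputDiscoveryError("; ".join(problems))

    raw_func = bids_dir / f"sub-{subject}" / "func"
    prep_func = fmriprep_dir / f"sub-{subject}" / "func"
    stem = f"sub-{subject}_task-{task}"
    space_pat = f"_space-{space}" if space else "_space-*"

    physio_tsv = _find_unique(
        raw_func, f"{stem}*_physio.tsv.gz",
        f"no physiological recording for task '{task}' (expected {stem}*_physio.tsv.gz)",
        problems,
    )
    physio_json = _find_unique(
        raw_func, f"{stem}*_physio.json",
        f"missing physio JSON sidecar {stem}*_physio.json", problems,
    )
    bold = _find_unique(
        prep_func, f"{stem}*{space_pat}_desc-preproc_bold.nii.gz",
        f"missing preprocessed BOLD {stem}*{space_pat}_desc-preproc_bold.nii.gz", problems,
    )
    mask = _find_unique(
        prep_func, f"{stem}*{space_pat}_desc-brain_mask.nii.gz",
        f"missing brain mask {stem}*{space_pat}_desc-brain_mask.nii.gz", problems,
    )
    mixing = _find_unique(
        prep_func, f"{stem}*_desc-MELODIC_mixing.tsv",
        "fMRIPrep must be run with ICA-AROMA (missing *_desc-MELODIC_mixing.tsv)", problems,
    )
    noise_ics = _find_unique(
        prep_func, f"{stem}*_AROMAnoiseICs.csv",
        "fMRIPrep must be run with ICA-AROMA (missing *_AROMAnoiseICs.csv)", problems,
    )
    if problems:
        raise InputDiscoveryError(
            f"dataset not suitable for CVR processing (subject {subject}): "
            + "; ".join(problems)
        )

    if space is None:
        space = parse_bids_name(bold).get("entities", {}).get("space", "native")
    tr = float(nib.load(str(bold)).header.get_zooms()[3])
    if not tr > 0:
        raise ValidationError(f"repetition time read from {bold.name} is not positive: {tr}")
    return ParticipantContext(
        subject=subject, task=task, space=space,
        bold_path=bold, mask_path=mask, mixing_path=mixing,
        noise_ics_path=noise_ics, physio_tsv=physio_tsv, physio_json=physio_json,
        tr=tr,
    )


def load_capno(context: ParticipantContext, co2_column: str = "co2") -> CapnoTrace:
    """Read the BIDS physio recording into a CapnoTrace (native units)."""
    meta = json.loads(context.physio_json.read_text())
    for key in ("SamplingFrequency", "Columns"):
        if key not in meta:
            raise ValidationError(f"physio sidecar {context.physio_json.name} lacks '{key}'")
    columns = list(meta["Columns"])
    if co2_column not in columns:
        raise ValidationError(
            f"column {co2_column!r} not in physio sidecar Columns {columns} "
            f"({context.physio_json.name})"
        )
    units = meta.get(co2_column, {}).get("Units")
    if units is None:
        raise ValidationError(
            f"physio sidecar {context.physio_json.name} lacks '{co2_column}'->'Units'"
        )
    table = pd.read_csv(context.physio_tsv, sep="\t", header=None, names=columns)
    return CapnoTrace(
        samples=table[co2_column].to_numpy(dtype=float),
        sampling_frequency=float(meta["SamplingFrequency"]),
        start_time=float(meta.get("StartTime", 0.0)),
        units=units,
    )


def load_bold(context: ParticipantContext) -> BoldVolume:
    return BoldVolume.from_files(context.bold_path, context.mask_path, tr=context.tr)


def load_ic_decomposition(context: ParticipantContext):
    """Read the MELODIC mixing matrix and the 1-based AROMA noise-IC list."""
    from .denoise import ICDecomposition

    mixing = np.loadtxt(context.mixing_path, ndmin=2)
    text = context.noise_ics_path.read_text().strip()
    indices = frozenset(int(tok) - 1 for tok in text.split(",") if tok.strip())
    return ICDecomposition(mixing=mixing, noise_indices=indices)


def _json_dump(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_derivatives(
    result,
    etco2: EtCO2Series,
    context: ParticipantContext,
    out_dir: str | Path,
    reclassification: pd.DataFrame | None = None,
    extra_metadata: dict | None = None,
) -> dict[str, Path]:
    """Write CVR/delay maps and companion tables as BIDS derivatives.

    The NIfTI maps inherit the preprocessed BOLD's affine and header; CVR is
    in %BOLD/mmHg, delay in seconds (global signal at 0).  Also writes the
    etCO2 timecourse (TSV + JSON), the IC reclassification table when
    available, and ``dataset_description.json`` documenting the suffix
    vocabulary.  Returns a name->path mapping of everything written.
    """
    out_dir = Path(out_dir)
    func_dir = out_dir / f"sub-{context.subject}" / "func"
    func_dir.mkdir(parents=True, exist_ok=True)

    from . import __version__

    _json_dump(
        out_dir / "dataset_description.json",
        {
            "Name": f"{PIPELINE_NAME} CVR derivatives",
            "BIDSVersion": "1.8.0",
            "DatasetType": "derivative",
            "GeneratedBy": [{"Name": PIPELINE_NAME, "Version": __version__}],
            "MapSuffixes": {
                "cvr": "cerebrovascular reactivity, %BOLD/mmHg",
                "delay": "hemodynamic delay, seconds, global signal referenced to 0",
            },
        },
    )

    src_img = nib.load(str(context.bold_path))
    entities = {"sub": context.subject, "task": context.task, "space": context.space}
    written: dict[str, Path] = {}

    def save_map(values: np.ndarray, suffix: str, meta: dict) -> None:
        img = nib.Nifti1Image(values.astype(np.float32), src_img.affine, src_img.header)
        img.header.set_data_dtype(np.float32)
        path = func_dir / build_bids_name(entities, suffix, ".nii.gz")
        nib.save(img, path)
        _json_dump(path.with_name(build_bids_name(entities, suffix, ".json")), meta)
        written[suffix] = path
        written[f"{suffix}_json"] = path.with_name(build_bids_name(entities, suffix, ".json"))

    common = dict(extra_metadata or {})
    save_map(result.cvr_map, "cvr", {"Units": "%BOLD/mmHg", **common})
    save_map(
        result.delay_map, "delay",
        {"Units": "s", "GlobalDelaySeconds": result.global_delay, **common},
    )

    etco2_entities = {"sub": context.subject, "task": context.task, "desc": "etco2"}
    etco2_tsv = func_dir / build_bids_name(etco2_entities, "timeseries", ".tsv")
    pd.DataFrame({"time": etco2.time_points, "etco2": etco2.values}).to_csv(
        etco2_tsv, sep="\t", index=False, float_format="%.6f"
    )
    fs = 1.0 / float(np.median(np.diff(etco2.time_points)))
    _json_dump(
        func_dir / build_bids_name(etco2_entities, "timeseries", ".json"),
        {
            "Columns": ["time", "etco2"],
            "Units": "mmHg",
            "SamplingFrequency": fs,
            "Baseline": etco2.baseline,
            "SourceSupport": list(etco2.source_support),
        },
    )
    written["etco2_tsv"] = etco2_tsv
    written["etco2_json"] = func_dir / build_bids_name(etco2_entities, "timeseries", ".json")

    if reclassification is not None:
        rc_entities = {"sub": context.subject, "task": context.task, "desc": "reclassification"}
        rc_path = func_dir / build_bids_name(rc_entities, "ics", ".tsv")
        reclassification.to_csv(rc_path, sep="\t", index=False)
        written["reclassification_tsv"] = rc_path

    written["dataset_description"] = out_dir / "dataset_description.json"
    return written
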