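"""Volume and table I/O: NIfTI volumes with a JSON channel sidecar, dual-echo
magnitude/phase pairs, ROI masks, clinical-score tables, and the run
configuration.

Conventions (BIDS-like): the 4-D stack stores one 3-D volume per channel;
the sidecar lists, per 4th-dimension index, the saturation offset in Hz
(signed; water = 0, agent side positive), the saturation amplitude in uT,
and an ``is_reference`` flag marking the single unsaturated acquisition.
The sagittal slice axis is the third voxel dimension.  Output volumes reuse
the input affine unchanged.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .b0 import DeltaB0Map, DualEchoPair
from .cest import CalibrationLine, ZSpectrumStack
from .synthetic import KOOS_SUBSCALES, SimulatedAcquisition, SubjectRecord

__all__ = [
    "RunConfig",
    "stack_from_acquisition",
    "write_stack",
    "read_stack",
    "write_volume",
    "read_volume",
    "write_dual_echo",
    "read_dual_echo",
    "write_records_csv",
    "read_records_csv",
    "write_calibration",
    "read_calibration",
]

COHORT_CSV_COLUMNS = [
    "subject_id", "group", "agent",
    *[f"koos_{s}" for s in KOOS_SUBSCALES], "vaps",
]


def _default_affine() -> np.ndarray:
    return np.eye(4)


def stack_from_acquisition(acq: SimulatedAcquisition) -> ZSpectrumStack:
    """View a simulated acquisition as the stack the analysis chain consumes."""
    return ZSpectrumStack(
        signals=acq.signals,
        channels=list(acq.channels),
        reference=acq.reference,
        water_frequency_mhz=acq.acquisition.water_frequency_mhz,
        affine=_default_affine(),
    )


def write_stack(stack: ZSpectrumStack, nii_path, sidecar_path=None) -> None:
    """Write the stack (saturation channels + reference last) and its sidecar."""
    nii_path = Path(nii_path)
    if sidecar_path is None:
        sidecar_path = nii_path.with_suffix("").with_suffix(".json") \
            if nii_path.name.endswith(".nii.gz") else nii_path.with_suffix(".json")
    data = np.concatenate(
        [stack.signals, stack.reference[..., None]], axis=-1
    )
    affine = stack.affine if stack.affine is not None else _default_affine()
    nib.save(nib.Nifti1Image(data.astype(np.float64), affine), str(nii_path))
    channels = [
        {"offset_hz": float(f), "b1_ut": float(b1), "is_reference": False}
        for f, b1 in stack.channels
    ]
    channels.append({"offset_hz": 0.0, "b1_ut": 0.0, "is_reference": True})
    sidecar = {
        "water_frequency_mhz": stack.water_frequency_mhz,
        "channels": channels,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_stack(nii_path, sidecar_path=None) -> ZSpectrumStack:
    """Load a 4-D stack, validating the sidecar against the volume.

    Raises on a channel-count mismatch, on multiple/missing reference
    channels, and on any saturation offset without its mirrored partner at
    the same power (named in the error).
    """
    nii_path = Path(nii_path)
    if sidecar_path is None:
        sidecar_path = nii_path.with_suffix("").with_suffix(".json") \
            if nii_path.name.endswith(".nii.gz") else nii_path.with_suffix(".json")
    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{nii_path}: expected a 4-D volume")
    sidecar = json.loads(Path(sidecar_path).read_text())
    chans = sidecar["channels"]
    if len(chans) != data.shape[-1]:
        raise ValueError(
            f"sidecar lists {len(chans)} channels but the volume has "
            f"{data.shape[-1]}"
        )
    ref_idx = [i for i, c in enumerate(chans) if c.get("is_reference")]
    if len(ref_idx) != 1:
        raise ValueError("sidecar must flag exactly one reference channel")
    sat = [(float(c["offset_hz"]), float(c["b1_ut"]))
           for i, c in enumerate(chans) if i not in ref_idx]
    pairs = set(sat)
    for f, b1 in sat:
        if (-f, b1) not in pairs:
            raise ValueError(
                f"offset {f:+.1f} Hz at {b1} uT has no {-f:+.1f} Hz partner"
            )
    keep = [i for i in range(len(chans)) if i not in ref_idx]
    return ZSpectrumStack(
        signals=data[..., keep],
        channels=sat,
        reference=data[..., ref_idx[0]],
        water_frequency_mhz=float(sidecar["water_frequency_mhz"]),
        affine=img.affine,
    )


def write_volume(volume: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    affine = affine if affine is not None else _default_affine()
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def write_dual_echo(acq_or_pair, out_dir, affine: np.ndarray | None = None) -> None:
    """Write the dual-echo pair as magnitude + phase NIfTI volumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(acq_or_pair, SimulatedAcquisition):
        pair = DualEchoPair(acq_or_pair.echo1, acq_or_pair.echo2,
                            acq_or_pair.acquisition.te1_ms,
                            acq_or_pair.acquisition.te2_ms)
    else:
        pair = acq_or_pair
    for name, vol in (("echo1", pair.echo1), ("echo2", pair.echo2)):
        write_volume(np.abs(vol), out / f"{name}_mag.nii.gz", affine)
        write_volume(np.angle(vol), out / f"{name}_phase.nii.gz", affine)
    (out / "echoes.json").write_text(json.dumps(
        {"te1_ms": pair.te1_ms, "te2_ms": pair.te2_ms}, indent=2))


def read_dual_echo(in_dir) -> DualEchoPair:
    indir = Path(in_dir)
    meta = json.loads((indir / "echoes.json").read_text())
    echoes = []
    for name in ("echo1", "echo2"):
        mag, _ = read_volume(indir / f"{name}_mag.nii.gz")
        phase, _ = read_volume(indir / f"{name}_phase.nii.gz")
        echoes.append(mag * np.exp(1j * phase))
    return DualEchoPair(echoes[0], echoes[1], meta["te1_ms"], meta["te2_ms"])


def write_b0_map(b0map: DeltaB0Map, out_dir, affine=None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(b0map.delta_f_hz, out / "b0.nii.gz", affine)
    write_volume(b0map.valid.astype(np.float64), out / "b0_mask.nii.gz", affine)


def read_b0_map(in_dir) -> DeltaB0Map:
    indir = Path(in_dir)
    delta, _ = read_volume(indir / "b0.nii.gz")
    valid, _ = read_volume(indir / "b0_mask.nii.gz")
    return DeltaB0Map(delta_f_hz=delta, valid=valid > 0.5)


def write_records_csv(records: list[SubjectRecord], path) -> None:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group, "agent": r.agent}
        row.update({f"koos_{s}": r.koos[s] for s in KOOS_SUBSCALES})
        row["vaps"] = r.vaps
        rows.append(row)
    pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS).to_csv(path, index=False)


def read_records_csv(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(COHORT_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(SubjectRecord(
            subject_id=str(row.subject_id), group=str(row.group),
            agent=str(row.agent),
            koos={s: float(row[f"koos_{s}"]) for s in KOOS_SUBSCALES},
            vaps=float(row.vaps),
        ))
    return records


def write_calibration(lines, path) -> None:
    """Serialize a calibration: one line, a per-label dict, or a per-agent
    dict of per-label dicts."""
    def one(ln: CalibrationLine) -> dict:
        return {"agent": ln.agent, "slope": ln.slope, "intercept": ln.intercept,
                "valid_ph_range": list(ln.valid_ph_range)}

    if isinstance(lines, dict):
        first = next(iter(lines))
        if isinstance(first, str):
            payload = {"per_agent": {
                agent: (one(sub) if isinstance(sub, CalibrationLine)
                        else {str(k): one(v) for k, v in sub.items()})
                for agent, sub in lines.items()}}
        else:
            payload = {"per_label": {str(k): one(v) for k, v in lines.items()}}
    else:
        payload = one(lines)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_calibration(path):
    payload = json.loads(Path(path).read_text())

    def one(d: dict) -> CalibrationLine:
        return CalibrationLine(d["agent"], d["slope"], d["intercept"],
                               tuple(d["valid_ph_range"]))
    if "per_agent" in payload:
        return {agent: (one(sub) if "slope" in sub
                        else {int(k): one(v) for k, v in sub.items()})
                for agent, sub in payload["per_agent"].items()}
    if "per_label" in payload:
        return {int(k): one(v) for k, v in payload["per_label"].items()}
    return one(payload)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Every pipeline parameter, serializable to/from YAML unchanged."""

    seed: int = 0
    n_no_oa: int = 9
    n_oa: int = 7
    matrix_size: tuple[int, int, int] = (24, 24, 28)
    noise_sigma: float = 0.02
    agent_override: str | None = None
    sigma: float = 1.0
    b0_limit_hz: float = 120.0
    magnitude_floor: float = 0.05
    calibration: str = "fitted"   # "fitted" | "builtin" | path to a JSON
    calibration_matrix_size: tuple[int, int, int] = (32, 32, 4)
    group_ph_means: dict = field(default_factory=lambda: {"no_oa": 7.01, "oa": 6.40})
    group_ph_sds: dict = field(default_factory=lambda: {"no_oa": 0.26, "oa": 0.08})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("matrix_size", "calibration_matrix_size"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg
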