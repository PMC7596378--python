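"""File formats and configuration.

EDF (European Data Format, 16-bit) is the interchange format for
recordings: this module writes EDF directly (fixed-layout headers,
one-second data records, physical dimension µV) and reads it through
mne after a lightweight header validation pass that fails closed on
truncated or malformed files. Cohorts travel as CSV with a documented
column schema and ``NA`` as the missing token; pipeline configuration
is YAML validated against a pydantic model that rejects unknown keys.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .features import BandDefinition, FeatureConfig
from .recording import EEGRecording
from .simulate import CohortDesign, SubjectRecord

__all__ = [
    "write_edf", "read_edf", "COHORT_COLUMNS", "cohort_frame",
    "write_cohort_csv", "read_cohort_csv", "PipelineConfig",
    "load_config", "config_hash",
]


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _fmt_float(v: float, width: int = 8) -> str:
    """Format a float into EDF's 8-char ascii numeric field, round-trip safe."""
    for prec in range(6, -1, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= width:
            return s
    return f"{v:.0f}"[:width]


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as 16-bit EDF with physical dimension µV.

    Data records are one second long, so the sampling rate must be an
    integer; the final partial record, if any, is zero-padded. The
    subject id goes into the local patient field and the gestational age
    into the local recording field (``GA_WEEKS=...``).
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writing requires an integer sampling rate")
    fs = int(round(fs))
    n_sig = rec.n_channels
    n_records = math.ceil(rec.n_samples / fs)

    pmax = float(np.abs(rec.data).max())
    if pmax <= 0:
        pmax = 1.0
    pmax_s = _fmt_float(pmax)
    pmin_s = _fmt_float(-pmax)
    pmax_used = float(pmax_s)  # scale with the value actually stored

    header = bytearray()
    header += _pad("0", 8)
    header += _pad(rec.subject_id or "X", 80)
    ga = "" if rec.ga_weeks is None else f" GA_WEEKS={rec.ga_weeks:g}"
    header += _pad(f"Startdate 01-JAN-2000{ga}", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (1 + n_sig)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)
    header += _pad(str(n_sig), 4)
    for lab in rec.channel_labels:
        header += _pad(lab, 16)
    for _ in range(n_sig):
        header += _pad("AgAgCl electrode", 80)
    for _ in range(n_sig):
        header += _pad("uV", 8)
    for _ in range(n_sig):
        header += _pad(pmin_s, 8)
    for _ in range(n_sig):
        header += _pad(pmax_s, 8)
    for _ in range(n_sig):
        header += _pad("-32768", 8)
    for _ in range(n_sig):
        header += _pad("32767", 8)
    for _ in range(n_sig):
        header += _pad("BP 0.1-45Hz", 80)
    for _ in range(n_sig):
        header += _pad(str(fs), 8)
    for _ in range(n_sig):
        header += _pad("", 32)

    gain = pmax_used / 32767.0
    padded = np.zeros((n_sig, n_records * fs))
    padded[:, : rec.n_samples] = rec.data
    digital = np.clip(np.round(padded / gain), -32768, 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            block = digital[:, r * fs: (r + 1) * fs]
            fh.write(block.tobytes())  # C order: signal-major within record


class EDFFormatError(ValueError):
    """Raised when an EDF file fails structural validation."""


def _validate_edf_header(path: Path) -> dict:
    size = path.stat().st_size
    if size < 256:
        raise EDFFormatError(
            f"{path}: file ends at byte {size}, before the 256-byte header")
    with open(path, "rb") as fh:
        head = fh.read(256)
    fields = {
        "version": (0, 8), "patient": (8, 88), "recording": (88, 168),
        "header_bytes": (184, 192), "n_records": (236, 244),
        "record_dur": (244, 252), "n_signals": (252, 256),
    }
    raw = {k: head[a:b].decode("ascii", errors="replace").strip()
           for k, (a, b) in fields.items()}
    if raw["version"] != "0":
        raise EDFFormatError(f"{path}: bad version field at byte 0: "
                             f"{raw['version']!r}")
    try:
        header_bytes = int(raw["header_bytes"])
        n_records = int(raw["n_records"])
        n_signals = int(raw["n_signals"])
        record_dur = float(raw["record_dur"])
    except ValueError as err:
        raise EDFFormatError(f"{path}: non-numeric header field near byte 184: "
                             f"{err}") from None
    expected_header = 256 * (1 + n_signals)
    if header_bytes != expected_header:
        raise EDFFormatError(
            f"{path}: header-bytes field at byte 184 says {header_bytes}, "
            f"expected {expected_header} for {n_signals} signals")
    if size < header_bytes:
        raise EDFFormatError(
            f"{path}: file ends at byte {size}, inside the "
            f"{header_bytes}-byte header")
    with open(path, "rb") as fh:
        full = fh.read(header_bytes)
    sig = full[256:]

    def sig_field(idx: int, width: int, offset: int) -> str:
        start = offset * n_signals + idx * width
        return sig[start: start + width].decode("ascii",
                                                errors="replace").strip()

    # per-signal blocks, sequential widths: 16,80,8,8,8,8,8,80,8,32
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    offsets = np.cumsum([0] + widths[:-1])
    labels, dims, samples = [], [], []
    for i in range(n_signals):
        labels.append(sig[offsets[0] * n_signals + i * 16:
                          offsets[0] * n_signals + (i + 1) * 16]
                      .decode("ascii", errors="replace").strip())
        d0 = offsets[2] * n_signals + i * 8
        dims.append(sig[d0: d0 + 8].decode("ascii", errors="replace").strip())
        s0 = offsets[8] * n_signals + i * 8
        try:
            samples.append(int(sig[s0: s0 + 8].decode("ascii").strip()))
        except ValueError:
            raise EDFFormatError(
                f"{path}: non-numeric samples-per-record field at byte "
                f"{256 + s0}") from None
    expected = header_bytes + n_records * sum(samples) * 2
    if size < expected:
        raise EDFFormatError(
            f"{path}: truncated at byte {size}; {expected} bytes expected "
            f"for {n_records} records")
    return {
        "patient": raw["patient"], "recording": raw["recording"],
        "n_signals": n_signals, "n_records": n_records,
        "record_dur": record_dur, "labels": labels, "dims": dims,
        "samples_per_record": samples,
    }


def read_edf(path) -> EEGRecording:
    """Read an EDF recording into an :class:`EEGRecording` (µV).

    The header is structurally validated first (clear errors with byte
    offsets; truncated files fail closed); signal parsing is delegated
    to mne, whose voltage data are converted back to µV. A physical
    dimension other than µV triggers a warning; the stored unit is
    converted through mne's SI normalisation.
    """
    import mne

    path = Path(path)
    meta = _validate_edf_header(path)
    for lab, dim in zip(meta["labels"], meta["dims"]):
        if dim not in ("uV", "µV"):
            warnings.warn(
                f"channel {lab!r} has physical dimension {dim!r}, not uV; "
                "converting through SI units", stacklevel=2)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    fs = float(raw.info["sfreq"])
    labels = tuple(meta["labels"])
    ga = None
    for token in meta["recording"].split():
        if token.startswith("GA_WEEKS="):
            ga = float(token.split("=", 1)[1])
    subject = meta["patient"]
    return EEGRecording(data_uv, fs, labels, subject_id=subject, ga_weeks=ga)


# --------------------------------------------------------------------------
# cohort CSV
# --------------------------------------------------------------------------

#: Column schema of the cohort CSV (missing token: ``NA``).
COHORT_COLUMNS = (
    "subject_id", "mutation", "treatment", "abnormal_eeg", "dysmature_eeg",
    "ied_present", "focal_slowing", "electrographic_seizure", "asd_24m",
    "ados_score", "verbal", "dq_cognitive", "dq_language", "dq_motor",
    "ga_first_eeg_weeks", "chron_age_first_eeg_days",
)

_BOOL_COLS = ("abnormal_eeg", "dysmature_eeg", "ied_present", "focal_slowing",
              "electrographic_seizure", "verbal")


def cohort_frame(records) -> pd.DataFrame:
    """Cohort records as a DataFrame in the documented column order."""
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id, "mutation": r.mutation,
            "treatment": r.treatment, "abnormal_eeg": r.abnormal_eeg,
            "dysmature_eeg": r.dysmature_eeg, "ied_present": r.ied_present,
            "focal_slowing": r.focal_slowing,
            "electrographic_seizure": r.electrographic_seizure,
            "asd_24m": r.asd_24m, "ados_score": r.ados_score,
            "verbal": r.verbal, "dq_cognitive": r.dq_cognitive,
            "dq_language": r.dq_language, "dq_motor": r.dq_motor,
            "ga_first_eeg_weeks": r.ga_first_eeg_weeks,
            "chron_age_first_eeg_days": r.chron_age_first_eeg_days,
        })
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort_csv(records, path) -> None:
    """Write a cohort as CSV with ``NA`` for missing values."""
    cohort_frame(records).to_csv(path, index=False, na_rep="NA")


def read_cohort_csv(path) -> list[SubjectRecord]:
    """Read and validate a cohort CSV.

    The column set must match the documented schema exactly; the
    composite abnormal-EEG invariant (abnormal iff IED, dysmature
    background, focal slowing or electrographic seizure) is re-checked
    for every row, and field-level validation (categorical levels, DQ
    range) happens in :class:`SubjectRecord`.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    got, want = list(df.columns), list(COHORT_COLUMNS)
    if got != want:
        raise ValueError(
            f"cohort CSV columns {got} do not match the schema {want}")
    records = []
    for i, row in df.iterrows():
        def get(col):
            v = row[col]
            return None if pd.isna(v) else v

        def get_bool(col):
            v = get(col)
            if v is None:
                return None
            if isinstance(v, (bool, np.bool_)):
                return bool(v)
            if str(v) in ("True", "False"):
                return str(v) == "True"
            raise ValueError(f"row {i}: non-boolean value {v!r} in {col!r}")

        rec = SubjectRecord(
            subject_id=str(row["subject_id"]),
            mutation=str(row["mutation"]),
            treatment=str(row["treatment"]),
            dysmature_eeg=get_bool("dysmature_eeg"),
            ied_present=get_bool("ied_present"),
            focal_slowing=get_bool("focal_slowing"),
            electrographic_seizure=get_bool("electrographic_seizure"),
            asd_24m=get_bool("asd_24m"),
            ados_score=None if get("ados_score") is None
                       else int(row["ados_score"]),
            verbal=get_bool("verbal"),
            dq_cognitive=get("dq_cognitive"),
            dq_language=get("dq_language"),
            dq_motor=get("dq_motor"),
            ga_first_eeg_weeks=float(row["ga_first_eeg_weeks"]),
            chron_age_first_eeg_days=float(row["chron_age_first_eeg_days"]),
        )
        stored = get_bool("abnormal_eeg")
        if stored != rec.abnormal_eeg:
            raise ValueError(
                f"row {i} ({rec.subject_id}): abnormal_eeg={stored} violates "
                "the composite invariant (IED, dysmature background, focal "
                "slowing or electrographic seizure)")
        records.append(rec)
    return records


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

class EEGSimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    duration_s: float = 120.0
    fs: float = 64.0
    channels: list[str] = Field(default_factory=lambda: ["C3", "C4", "O1", "O2"])


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 24
    p_dysmature: float = 14 / 63
    p_asd_given_dysmature: float = 8 / 14
    p_asd_given_mature: float = 11 / 49
    n_missing_outcome: int = 1

    def to_design(self) -> CohortDesign:
        return CohortDesign(
            p_dysmature=self.p_dysmature,
            p_asd_given_dysmature=self.p_asd_given_dysmature,
            p_asd_given_mature=self.p_asd_given_mature,
            n_missing_outcome=self.n_missing_outcome)


class FeaturesSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bands: dict[str, tuple[float, float]] = Field(default_factory=lambda: {
        "delta1": (0.5, 2.0), "delta2": (2.0, 4.0), "theta": (4.0, 8.0),
        "alpha": (8.0, 16.0), "beta": (16.0, 30.0)})
    reeg_window_s: float = 2.0
    mse_m: int = 2
    mse_r: float = 0.2
    mse_max_scale: int = 20
    mse_fixed_r: bool = False
    mse_max_samples: int = 3840
    hurst_max_samples: int = 16384

    def to_feature_config(self) -> FeatureConfig:
        bands = tuple(BandDefinition(k, lo, hi)
                      for k, (lo, hi) in self.bands.items())
        return FeatureConfig(
            bands=bands, reeg_window_s=self.reeg_window_s, mse_m=self.mse_m,
            mse_r=self.mse_r, mse_max_scale=self.mse_max_scale,
            mse_fixed_r=self.mse_fixed_r, mse_max_samples=self.mse_max_samples,
            hurst_max_samples=self.hurst_max_samples)


class ClassifierConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_features: int = 5
    folds: int = 3
    repetitions: int = 1


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    eeg: EEGSimConfig = Field(default_factory=EEGSimConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    features: FeaturesSection = Field(default_factory=FeaturesSection)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def config_hash(config: PipelineConfig) -> str:
    """Short provenance hash of the resolved configuration."""
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
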