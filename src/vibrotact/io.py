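"""CSV interchange for traces, spectra, features and metadata."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .signals import AmplitudeSpectrum, SampleMetadata, VibrationTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_metadata_csv",
    "write_spectrum_csv",
    "read_spectrum_csv",
]


def read_trace_csv(
    path,
    sample_id: str = "",
    repetition: int = 1,
    unit: str = "volt",
    sampling_rate: float | None = None,
) -> VibrationTrace:
    """Load a trace from a time_s,value CSV.

    The sampling rate is inferred from the time column unless given.
    """
    df = pd.read_csv(path)
    if not {"time_s", "value"} <= set(df.columns):
        raise ValueError("trace CSV needs time_s and value columns")
    if sampling_rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("non-uniform time column; pass sampling_rate explicitly")
        sampling_rate = 1.0 / dt[0]
    return VibrationTrace(
        sample_id=sample_id or str(path),
        repetition=repetition,
        sampling_rate=float(sampling_rate),
        values=df["value"].to_numpy(float),
        unit=unit,
    )


def write_trace_csv(trace: VibrationTrace, path) -> None:
    t = np.arange(trace.values.size) / trace.sampling_rate
    pd.DataFrame({"time_s": t, "value": trace.values}).to_csv(path, index=False)


def read_metadata_csv(path) -> dict[str, SampleMetadata]:
    """sample_id, mu_prime[, ra_um, wa_um, normal_force_n] -> metadata map."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        out[str(row["sample_id"])] = SampleMetadata(
            sample_id=str(row["sample_id"]),
            mu_prime=float(row["mu_prime"]),
            ra_um=float(row["ra_um"]) if "ra_um" in row and pd.notna(row.get("ra_um")) else None,
            wa_um=float(row["wa_um"]) if "wa_um" in row and pd.notna(row.get("wa_um")) else None,
            normal_force_n=(
                float(row["normal_force_n"])
                if "normal_force_n" in row and pd.notna(row.get("normal_force_n"))
                else None
            ),
        )
    return out


def write_spectrum_csv(spec: AmplitudeSpectrum, path) -> None:
    pd.DataFrame(
        {"frequency_hz": spec.frequencies, "amplitude_um": spec.amplitudes}
    ).to_csv(path, index=False)


def read_spectrum_csv(path, window: str = "hamming") -> AmplitudeSpectrum:
    df = pd.read_csv(path)
    return AmplitudeSpectrum(
        frequencies=df["frequency_hz"].to_numpy(float),
        amplitudes=df["amplitude_um"].to_numpy(float),
        window=window,
        n_fft=2 * (len(df) - 1),
    )
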