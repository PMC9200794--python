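"""Numeric DNA encodings, DFT power spectra and spectral descriptors.

Five encodings are supported: 4-channel binary indicators, an integer
mapping, a real-number mapping, the cumulative 3-D Z-curve and the EIIP
(electron-ion interaction pseudopotential) values.  Each encoding is turned
into a power spectrum via the FFT (no zero-padding: exactly L bins, DC
included) and summarized by 18 statistics; the concatenation over all five
encodings is the 90-dimensional spectral descriptor vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .errors import ConfigError, DegenerateSpectrumError, EmptySequenceError
from .features import FeatureSchema, FeatureVector
from .io import SequenceRecord

SCHEMES = ("binary", "integer", "real", "zcurve", "eiip")

INTEGER_MAP = {"T": 0.0, "C": 1.0, "A": 2.0, "G": 3.0}
REAL_MAP = {"A": -1.5, "G": -0.5, "C": 0.5, "T": 1.5}
EIIP_MAP = {"G": 0.0806, "A": 0.1260, "T": 0.1335, "C": 0.1340}

DESCRIPTOR_NAMES = (
    "papr",
    "snr",
    "min",
    "max",
    "median",
    "std_pop",
    "std_samp",
    "p15",
    "p25",
    "p50",
    "p75",
    "variance",
    "cv",
    "amplitude",
    "semi_iqr",
    "iqr",
    "skewness",
    "kurtosis",
)


@dataclass(frozen=True)
class NumericSignal:
    """One or more equal-length real-valued channels for a sequence."""

    scheme: str
    channels: np.ndarray  # shape (n_channels, L)

    @property
    def length(self) -> int:
        return self.channels.shape[1]


def _as_array(residues: str) -> np.ndarray:
    return np.frombuffer(residues.encode("ascii"), dtype=np.uint8)


def encode(seq: SequenceRecord | str, scheme: str) -> NumericSignal:
    """Map a sequence onto the named numeric representation."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if not residues:
        raise EmptySequenceError("cannot encode an empty sequence")
    if scheme not in SCHEMES:
        raise ConfigError(f"unknown encoding scheme: {scheme!r}")
    arr = _as_array(residues)
    if scheme == "binary":
        channels = np.stack([(arr == ord(b)).astype(float) for b in "ACGT"])
    elif scheme == "zcurve":
        a = np.cumsum(arr == ord("A"))
        c = np.cumsum(arr == ord("C"))
        g = np.cumsum(arr == ord("G"))
        t = np.cumsum(arr == ord("T"))
        x = (a + g) - (c + t)
        y = (a + c) - (g + t)
        z = (a + t) - (c + g)
        channels = np.stack([x, y, z]).astype(float)
    else:
        table = {"integer": INTEGER_MAP, "real": REAL_MAP, "eiip": EIIP_MAP}[scheme]
        lut = np.zeros(256)
        for base, value in table.items():
            lut[ord(base)] = value
        channels = lut[arr][None, :]
    return NumericSignal(scheme=scheme, channels=channels)


def power_spectrum(sig: NumericSignal) -> np.ndarray:
    """Squared DFT magnitudes, summed over channels; length L, DC included."""
    spectra = np.abs(np.fft.fft(sig.channels, axis=1)) ** 2
    return spectra.sum(axis=0)


def descriptors(ps: np.ndarray, include_dc: bool = True) -> np.ndarray:
    """The 18 spectral statistics of a power spectrum.

    PAPR = max/mean; SNR = P[round(L/3)]/mean (the period-3 bin of coding
    sequences); CV = population std / mean.  Kurtosis is non-excess (normal
    -> 3); percentiles use linear interpolation.  ``include_dc=False`` drops
    the f=0 bin before computing everything (SNR still indexes the original
    spectrum).
    """
    ps = np.asarray(ps, dtype=float)
    full_len = ps.size
    if full_len < 2:
        raise ValueError("descriptors need a spectrum of length >= 2")
    snr_bin = round(full_len / 3)
    snr_power = ps[snr_bin % full_len]
    values = ps if include_dc else ps[1:]
    mean = values.mean()
    if mean == 0:
        raise DegenerateSpectrumError("all-zero spectrum: PAPR/SNR/CV undefined")
    std_pop = values.std(ddof=0)
    p15, p25, p50, p75 = np.percentile(values, [15, 25, 50, 75])
    iqr = p75 - p25
    if std_pop > 0:
        skewness = sstats.skew(values, bias=True)
        kurt = sstats.kurtosis(values, fisher=False, bias=True)
    else:
        skewness = kurt = 0.0  # constant spectrum: moments degenerate
    return np.array(
        [
            values.max() / mean,
            snr_power / mean,
            values.min(),
            values.max(),
            np.median(values),
            std_pop,
            values.std(ddof=1),
            p15,
            p25,
            p50,
            p75,
            values.var(ddof=0),
            std_pop / mean,
            values.max() - values.min(),
            iqr / 2.0,
            iqr,
            skewness,
            kurt,
        ]
    )


def rff_schema() -> FeatureSchema:
    """Schema of the fused spectral descriptor space: 5 encodings x 18 stats."""
    return FeatureSchema.from_blocks(
        [
            (scheme, [f"{scheme}_{stat}" for stat in DESCRIPTOR_NAMES])
            for scheme in SCHEMES
        ]
    )


def rff_vector(seq: SequenceRecord, include_dc: bool = True) -> FeatureVector:
    """Concatenated spectral descriptors over all five encodings."""
    if len(seq.residues) < 2:
        raise EmptySequenceError(
            f"record {seq.id!r}: spectral descriptors need length >= 2"
        )
    parts = [
        descriptors(power_spectrum(encode(seq, scheme)), include_dc=include_dc)
        for scheme in SCHEMES
    ]
    return FeatureVector(
        record_id=seq.id, values=np.concatenate(parts), schema=rff_schema()
    )
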