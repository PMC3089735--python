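"""Modified Beer-Lambert law (MBLL) chromophore conversion.

Converts between two-wavelength optical-density changes and
oxy-/deoxyhaemoglobin concentration changes (``uM``), using an
age-dependent differential pathlength factor (DPF) of the form
``DPF(age) = a + b * age**c``.

Units
-----
* concentrations: uM (umol/L)
* source-detector separations: cm
* specific extinction coefficients: cm^-1 uM^-1
* optical-density changes: dimensionless (base-10 attenuation change)

The extinction-coefficient and DPF-coefficient tables ship as small,
cited, user-replaceable CSV files under :mod:`nirsbp.data`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "OpticalGeometry",
    "ExtinctionTable",
    "DpfModel",
    "OpticalChannel",
    "RawOpticalRecording",
    "ChromophoreRecording",
    "dpf",
    "mbll_matrix",
    "od_to_conc",
    "conc_to_od",
]

#: maximum acceptable condition number of the 2x2 extinction system
CONDITION_LIMIT = 1e6

DEFAULT_WAVELENGTHS_NM = (764.0, 859.0)
DEEP_SEPARATION_CM = 4.0
SHALLOW_SEPARATION_CM = 1.0


@dataclass(frozen=True)
class OpticalGeometry:
    """Measurement geometry of one NIRS channel."""

    wavelengths_nm: tuple[float, float] = DEFAULT_WAVELENGTHS_NM
    separation_cm: float = DEEP_SEPARATION_CM
    age_years: float = 25.0

    def __post_init__(self) -> None:
        w1, w2 = self.wavelengths_nm
        if w1 == w2:
            raise ValueError("wavelengths must be distinct")
        if self.separation_cm <= 0:
            raise ValueError("source-detector separation must be > 0")
        if self.age_years < 0:
            raise ValueError("age must be >= 0")


class ExtinctionTable:
    """Specific extinction coefficients for O2Hb and HHb vs wavelength.

    Parameters
    ----------
    wavelengths_nm, eps_o2hb, eps_hhb
        Tabulated wavelengths (strictly increasing) and the matching
        coefficients in cm^-1 uM^-1. Queries are linearly interpolated.
    citation
        Free-text provenance of the coefficient values.
    """

    def __init__(
        self,
        wavelengths_nm: np.ndarray,
        eps_o2hb: np.ndarray,
        eps_hhb: np.ndarray,
        citation: str = "",
    ) -> None:
        wl = np.asarray(wavelengths_nm, dtype=float)
        eo = np.asarray(eps_o2hb, dtype=float)
        eh = np.asarray(eps_hhb, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("need at least two tabulated wavelengths")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("tabulated wavelengths must be strictly increasing")
        if np.any(eo <= 0) or np.any(eh <= 0):
            raise ValueError("extinction coefficients must be positive")
        self.wavelengths_nm = wl
        self.eps_o2hb = eo
        self.eps_hhb = eh
        self.citation = citation

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """Load the packaged haemoglobin extinction table."""
        src = resources.files("nirsbp.data").joinpath("extinction_hb.csv")
        with resources.as_file(src) as path:
            df = pd.read_csv(path, comment="#")
        return cls(
            df["wavelength_nm"].to_numpy(),
            df["eps_o2hb_cm1_uM1"].to_numpy(),
            df["eps_hhb_cm1_uM1"].to_numpy(),
            citation=(
                "Prahl OMLC compiled haemoglobin spectra (1999), "
                "converted to cm^-1 uM^-1"
            ),
        )

    def _check_range(self, wavelength_nm: float) -> None:
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if not lo <= wavelength_nm <= hi:
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside tabulated range "
                f"[{lo}, {hi}] nm"
            )

    def eps(self, wavelength_nm: float) -> tuple[float, float]:
        """Return ``(eps_o2hb, eps_hhb)`` at a wavelength (interpolated)."""
        self._check_range(wavelength_nm)
        eo = float(np.interp(wavelength_nm, self.wavelengths_nm, self.eps_o2hb))
        eh = float(np.interp(wavelength_nm, self.wavelengths_nm, self.eps_hhb))
        return eo, eh


@dataclass(frozen=True)
class DpfModel:
    """Per-wavelength ``(a, b, c)`` coefficients of ``DPF = a + b*age**c``."""

    coefficients: dict[float, tuple[float, float, float]]
    citation: str = ""
    #: wavelengths closer than this to a table entry resolve to it (nm)
    match_tol_nm: float = 0.5

    def __post_init__(self) -> None:
        for wl, (a, _b, _c) in self.coefficients.items():
            if a <= 0:
                raise ValueError(f"DPF intercept must be positive at {wl} nm")

    @classmethod
    def default(cls) -> "DpfModel":
        src = resources.files("nirsbp.data").joinpath("dpf_age.csv")
        with resources.as_file(src) as path:
            df = pd.read_csv(path, comment="#")
        coeffs = {
            float(r.wavelength_nm): (float(r.a), float(r.b), float(r.c))
            for r in df.itertuples()
        }
        return cls(coeffs, citation="Duncan et al. 1996 cranial DPF vs age")

    def lookup(self, wavelength_nm: float) -> tuple[float, float, float]:
        for wl, abc in self.coefficients.items():
            if abs(wl - wavelength_nm) <= self.match_tol_nm:
                return abc
        avail = ", ".join(f"{w:g}" for w in sorted(self.coefficients))
        raise KeyError(
            f"no DPF coefficients for {wavelength_nm} nm; available: {avail} nm"
        )


def dpf(age_years: float, wavelength_nm: float, model: DpfModel | None = None) -> float:
    """Differential pathlength factor ``a + b * age**c`` at one wavelength.

    Raises
    ------
    KeyError
        If the model has no coefficients for ``wavelength_nm``.
    """
    if model is None:
        model = DpfModel.default()
    if age_years < 0:
        raise ValueError("age must be >= 0")
    a, b, c = model.lookup(wavelength_nm)
    return a + b * age_years**c


@dataclass
class OpticalChannel:
    """One channel of a raw optical recording.

    ``od`` has shape ``(n_samples, 2)``: optical-density change at each of
    the recording's two wavelengths.
    """

    label: str
    separation_cm: float
    od: np.ndarray
    mode: str = "deep"  # "deep" (cortical path) or "shallow" (extracranial)

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 2 or self.od.shape[1] != 2:
            raise ValueError("channel od must have shape (n_samples, 2)")
        if self.mode not in ("deep", "shallow"):
            raise ValueError(f"unknown channel mode {self.mode!r}")


@dataclass
class RawOpticalRecording:
    """Uniformly sampled two-wavelength optical-density changes."""

    time_s: np.ndarray
    channels: list[OpticalChannel]
    wavelengths_nm: tuple[float, float] = DEFAULT_WAVELENGTHS_NM
    age_years: float = 25.0
    fs_hz: float = 50.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        n = self.time_s.size
        for ch in self.channels:
            if ch.od.shape[0] != n:
                raise ValueError(
                    f"channel {ch.label}: {ch.od.shape[0]} samples, "
                    f"time axis has {n}"
                )

    def geometry(self, channel: OpticalChannel) -> OpticalGeometry:
        return OpticalGeometry(self.wavelengths_nm, channel.separation_cm, self.age_years)


@dataclass
class ChromophoreRecording:
    """Per-channel O2Hb / HHb concentration changes in uM."""

    time_s: np.ndarray
    o2hb: dict[str, np.ndarray] = field(default_factory=dict)
    hhb: dict[str, np.ndarray] = field(default_factory=dict)
    fs_hz: float = 50.0

    @property
    def channel_labels(self) -> list[str]:
        return list(self.o2hb)


def mbll_matrix(
    geometry: OpticalGeometry,
    ext: ExtinctionTable | None = None,
    dpfm: DpfModel | None = None,
) -> np.ndarray:
    """Forward 2x2 system mapping ``(dO2Hb, dHHb)`` in uM to ``dOD``.

    Row i corresponds to wavelength i:
    ``dOD(l_i) = (eps_o2hb(l_i)*dC_o2hb + eps_hhb(l_i)*dC_hhb) * d * DPF(l_i)``.

    Raises
    ------
    ValueError
        If the system is singular or ill-conditioned for the requested
        wavelength pair.
    """
    if ext is None:
        ext = ExtinctionTable.default()
    if dpfm is None:
        dpfm = DpfModel.default()
    rows = []
    for wl in geometry.wavelengths_nm:
        eo, eh = ext.eps(wl)
        path = geometry.separation_cm * dpf(geometry.age_years, wl, dpfm)
        rows.append([eo * path, eh * path])
    m = np.array(rows, dtype=float)
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise ValueError(
            f"extinction system at {geometry.wavelengths_nm} nm is "
            f"ill-conditioned (cond={cond:.3g})"
        )
    return m


def od_to_conc(
    raw: RawOpticalRecording,
    ext: ExtinctionTable | None = None,
    dpfm: DpfModel | None = None,
) -> ChromophoreRecording:
    """Invert the MBLL per sample: optical densities -> concentrations (uM)."""
    out = ChromophoreRecording(time_s=raw.time_s.copy(), fs_hz=raw.fs_hz)
    for ch in raw.channels:
        m = mbll_matrix(raw.geometry(ch), ext, dpfm)
        conc = np.linalg.solve(m, ch.od.T)  # (2, n)
        out.o2hb[ch.label] = conc[0]
        out.hhb[ch.label] = conc[1]
    return out


def conc_to_od(
    conc: ChromophoreRecording,
    raw_template: RawOpticalRecording,
    ext: ExtinctionTable | None = None,
    dpfm: DpfModel | None = None,
) -> RawOpticalRecording:
    """Forward MBLL: concentrations (uM) -> optical densities.

    ``raw_template`` supplies geometry (wavelengths, per-channel
    separations, age); its od arrays are ignored and replaced.
    Exact algebraic inverse of :func:`od_to_conc`.
    """
    channels = []
    for ch in raw_template.channels:
        m = mbll_matrix(raw_template.geometry(ch), ext, dpfm)
        c = np.vstack([conc.o2hb[ch.label], conc.hhb[ch.label]])  # (2, n)
        od = (m @ c).T  # (n, 2)
        channels.append(OpticalChannel(ch.label, ch.separation_cm, od, ch.mode))
    return RawOpticalRecording(
        time_s=conc.time_s.copy(),
        channels=channels,
        wavelengths_nm=raw_template.wavelengths_nm,
        age_years=raw_template.age_years,
        fs_hz=raw_template.fs_hz,
    )
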