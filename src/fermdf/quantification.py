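"""Raw-measurement → concentration conversions and dataset containers.

Extracellular metabolites (HPLC) arrive already calibrated in mM or g/L.
Intracellular metabolites (LC-MS) arrive either as absolute mM or as peak
areas that must be converted through an external-standard calibration curve
and the total intracellular volume on the filter:

    V_intracellular = single-cell volume × OD600 × cells/mL at OD600 = 1
                      × volume of culture filtered

All concentrations are user-facing in mM; thermodynamic code consumes molar.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CellParams",
    "CELL_PARAMS",
    "CalibrationCurve",
    "FermentationDataset",
    "cell_volume_from_dimensions",
    "um3_to_ml",
    "intracellular_volume",
    "fit_calibration",
    "peak_to_concentration",
    "mm_to_gl",
    "gl_to_mm",
    "MOLAR_MASS",
    "zscore_matrix",
]

#: Molar masses (g/mol) for the worked-example conversions.
MOLAR_MASS = {
    "etoh": 46.069,
    "glc": 180.156,
    "cb": 342.297,
    "pyr": 88.06,
}


@dataclass(frozen=True)
class CellParams:
    """Microscopy-derived cell geometry and counting calibration.

    ``single_cell_volume`` is in mL per cell; ``cells_per_ml_at_od1`` is the
    cell count per mL of culture at OD600 = 1.
    """

    single_cell_volume: float
    cells_per_ml_at_od1: float

    def __post_init__(self) -> None:
        if self.single_cell_volume <= 0 or self.cells_per_ml_at_od1 <= 0:
            raise ValueError("cell parameters must be strictly positive")


#: Reported per-organism cell parameters: volumes of ~0.7, 0.5 and 4.5 µm³ and
#: counts of 8.9e8, 4.4e8 and 2.2e8 cells/mL at OD600 = 1.
CELL_PARAMS = {
    "eco": CellParams(7e-13, 8.9e8),
    "tsac": CellParams(5e-13, 4.4e8),
    "zmo": CellParams(4.5e-12, 2.2e8),
}


def cell_volume_from_dimensions(radius_um: float, length_um: float) -> float:
    """Cylinder approximation of a rod-shaped cell: π·r²·L, in µm³."""
    if radius_um <= 0 or length_um <= 0:
        raise ValueError("radius and length must be strictly positive")
    return math.pi * radius_um**2 * length_um


def um3_to_ml(volume_um3: float) -> float:
    """Convert µm³ to mL (1 µm³ = 1e-12 mL)."""
    return volume_um3 * 1e-12


def intracellular_volume(od: float, vol_filtered_ml: float, params: CellParams) -> float:
    """Total intracellular volume (mL) collected on a filter.

    Product of single-cell volume, OD600, cells/mL at OD600 = 1 and the
    filtered culture volume; linear in both ``od`` and ``vol_filtered_ml``.
    """
    if od < 0:
        raise ValueError("od must be non-negative")
    if vol_filtered_ml <= 0:
        raise ValueError("filtered volume must be strictly positive")
    return params.single_cell_volume * od * params.cells_per_ml_at_od1 * vol_filtered_ml


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear external-standard calibration: area = slope·amount + intercept.

    ``slope`` is peak-area per mol of analyte; ``intercept`` in peak-area
    units; ``fit_r2`` records the goodness of the OLS fit.
    """

    metabolite_id: str
    slope: float
    intercept: float = 0.0
    fit_r2: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not 0.0 <= self.fit_r2 <= 1.0:
            raise ValueError("fit_r2 must lie in [0, 1]")


def fit_calibration(
    metabolite_id: str, amounts_mol: np.ndarray, areas: np.ndarray
) -> CalibrationCurve:
    """OLS fit (free intercept) of peak area against known standard amounts."""
    amounts = np.asarray(amounts_mol, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if amounts.size < 2:
        raise ValueError("need at least 2 standards to fit a calibration")
    slope, intercept = np.polyfit(amounts, areas, 1)
    pred = slope * amounts + intercept
    ss_res = float(np.sum((areas - pred) ** 2))
    ss_tot = float(np.sum((areas - areas.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return CalibrationCurve(metabolite_id, float(slope), float(intercept), r2)


def peak_to_concentration(
    area: float, cal: CalibrationCurve, intracellular_vol_ml: float
) -> float:
    """Convert a peak area to an intracellular concentration in mM.

    Inverts the calibration to an amount in mol and divides by the
    intracellular volume.  Areas below the calibration intercept are below
    the quantification limit and clip to 0 mM with a warning.
    """
    if intracellular_vol_ml <= 0:
        raise ValueError("intracellular volume must be strictly positive")
    amount_mol = (area - cal.intercept) / cal.slope
    if amount_mol < 0:
        warnings.warn(
            f"{cal.metabolite_id}: peak area below calibration intercept; "
            "reporting 0 mM (below quantification limit)",
            stacklevel=2,
        )
        return 0.0
    # mol / mL = 1000 mol/L = 1e6 mM
    return amount_mol / intracellular_vol_ml * 1e6


def mm_to_gl(conc_mm: float, molar_mass: float) -> float:
    """mM → g/L (conc × molar mass / 1000)."""
    if conc_mm < 0:
        raise ValueError("concentration must be non-negative")
    return conc_mm * molar_mass / 1000.0


def gl_to_mm(conc_gl: float, molar_mass: float) -> float:
    """g/L → mM."""
    if conc_gl < 0:
        raise ValueError("concentration must be non-negative")
    return conc_gl * 1000.0 / molar_mass


def zscore_matrix(peaks: pd.DataFrame | dict) -> pd.DataFrame:
    """Z-score each metabolite's series across its own time points.

    Accepts a metabolite × time DataFrame (rows = metabolites) or a mapping
    metabolite → series.  Uses the sample standard deviation (ddof=1);
    constant rows map to all-zero rows; rows with fewer than 2 finite points
    are dropped with a warning.
    """
    if isinstance(peaks, dict):
        mat = pd.DataFrame({k: pd.Series(v) for k, v in peaks.items()}).T
    else:
        mat = peaks.copy()
    out = {}
    for met, row in mat.iterrows():
        vals = row.astype(float)
        if vals.notna().sum() < 2:
            warnings.warn(f"{met}: fewer than 2 points; excluded from z-scores",
                          stacklevel=2)
            continue
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            out[met] = vals * 0.0
        else:
            out[met] = (vals - vals.mean()) / sd
    return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# Dataset container and long-format CSV I/O
# ---------------------------------------------------------------------------

_SERIES_TYPES = ("od", "extracellular", "intracellular_mM", "intracellular_area")


@dataclass
class FermentationDataset:
    """Time-resolved fermentation measurements on a shared time grid.

    ``extracellular`` and ``intracellular_mm`` are time × metabolite
    DataFrames in mM; ``intracellular_area`` holds raw LC-MS peak areas where
    absolute calibration is unavailable.  ``filtered_volume_ml`` is the
    per-sample filtered culture volume used for intracellular quantification.
    """

    time_h: np.ndarray
    od: pd.Series
    extracellular: pd.DataFrame
    intracellular_mm: pd.DataFrame
    intracellular_area: pd.DataFrame | None = None
    filtered_volume_ml: pd.Series | None = None
    phase_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("need at least two time points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        self.time_h = t
        for name, obj in (("od", self.od), ("extracellular", self.extracellular),
                          ("intracellular_mm", self.intracellular_mm)):
            if len(obj) != len(t):
                raise ValueError(f"{name} does not share the time index")
        for df in (self.extracellular, self.intracellular_mm):
            with np.errstate(invalid="ignore"):
                if (df.to_numpy(dtype=float) < 0).any():
                    raise ValueError("concentrations must be non-negative")

    @property
    def n_timepoints(self) -> int:
        return len(self.time_h)

    def intracellular_at(self, i: int) -> dict[str, float]:
        """Measured intracellular mM at time index ``i`` (finite values only)."""
        row = self.intracellular_mm.iloc[i]
        return {m: float(v) for m, v in row.items() if np.isfinite(v)}

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        fv = (self.filtered_volume_ml if self.filtered_volume_ml is not None
              else pd.Series([np.nan] * self.n_timepoints))
        for i, t in enumerate(self.time_h):
            rows.append((t, "od", "od", float(self.od.iloc[i]), float(fv.iloc[i])))
            for df, stype in ((self.extracellular, "extracellular"),
                              (self.intracellular_mm, "intracellular_mM"),
                              (self.intracellular_area, "intracellular_area")):
                if df is None:
                    continue
                for met in df.columns:
                    v = df.iloc[i][met]
                    if np.isfinite(v):
                        rows.append((t, stype, met, float(v), float(fv.iloc[i])))
        return pd.DataFrame(
            rows, columns=["time_h", "series_type", "metabolite", "value",
                           "filtered_volume_ml"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "FermentationDataset":
        bad = set(frame["series_type"]) - set(_SERIES_TYPES)
        if bad:
            raise ValueError(f"unknown series_type values: {sorted(bad)}")
        time = np.sort(frame["time_h"].unique())
        od_rows = frame[frame["series_type"] == "od"].set_index("time_h")
        od = od_rows["value"].reindex(time)

        def pivot(stype: str) -> pd.DataFrame:
            sub = frame[frame["series_type"] == stype]
            if sub.empty:
                return pd.DataFrame(index=pd.Index(time, name="time_h"))
            wide = sub.pivot_table(index="time_h", columns="metabolite",
                                   values="value", aggfunc="mean")
            return wide.reindex(time)

        fv = None
        if frame["filtered_volume_ml"].notna().any():
            fv = (frame.dropna(subset=["filtered_volume_ml"])
                  .groupby("time_h")["filtered_volume_ml"].first().reindex(time))
        area = pivot("intracellular_area")
        return cls(
            time_h=time,
            od=od.reset_index(drop=True),
            extracellular=pivot("extracellular").reset_index(drop=True),
            intracellular_mm=pivot("intracellular_mM").reset_index(drop=True),
            intracellular_area=None if area.shape[1] == 0 else area.reset_index(drop=True),
            filtered_volume_ml=None if fv is None else fv.reset_index(drop=True),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FermentationDataset":
        return cls.from_long_frame(pd.read_csv(path))

    def quantify_areas(
        self, calibrations: dict[str, CalibrationCurve], params: CellParams
    ) -> "FermentationDataset":
        """Convert peak-area series to mM using per-sample intracellular volume.

        Returns a new dataset whose ``intracellular_mm`` is augmented with the
        calibrated metabolites (existing absolute columns are kept).
        """
        if self.intracellular_area is None:
            raise ValueError("dataset has no peak-area series")
        if self.filtered_volume_ml is None:
            raise ValueError("peak-area quantification needs filtered volumes")
        conc = self.intracellular_mm.copy()
        for met in self.intracellular_area.columns:
            if met not in calibrations:
                warnings.warn(f"no calibration for {met}; left unquantified",
                              stacklevel=2)
                continue
            cal = calibrations[met]
            vals = []
            for i in range(self.n_timepoints):
                area = self.intracellular_area.iloc[i][met]
                if not np.isfinite(area):
                    vals.append(np.nan)
                    continue
                icv = intracellular_volume(
                    float(self.od.iloc[i]), float(self.filtered_volume_ml.iloc[i]),
                    params)
                if icv <= 0:
                    vals.append(np.nan)
                    continue
                vals.append(peak_to_concentration(area, cal, icv))
            conc[met] = vals
        return FermentationDataset(
            time_h=self.time_h.copy(),
            od=self.od.copy(),
            extracellular=self.extracellular.copy(),
            intracellular_mm=conc,
            intracellular_area=self.intracellular_area.copy(),
            filtered_volume_ml=self.filtered_volume_ml.copy(),
            phase_labels=None if self.phase_labels is None else self.phase_labels.copy(),
        )
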