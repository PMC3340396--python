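"""Underwater spectral optics: waveband quanta, diffuse attenuation, color ratios.

Turns hyperspectral depth profiles of downwelling irradiance Ed(lambda, z)
into the quantities that summarise the underwater light climate of a river
reach:

* quanta-integrated waveband irradiance (photon flux, umol photons m-2 s-1),
* the diffuse attenuation coefficient K_d (m-1) per waveband, fitted by
  linear regression of ln(irradiance) on depth,
* the 1% penetration depth z1% = 4.6 / K_d and the photic fraction of the
  water column,
* spectral color ratios (blue/red, green/red) describing the relative
  penetration of wavebands, and
* conversion of lab absorbance to the CDOM absorption coefficient aCDOM.

CDOM (chromophoric dissolved organic matter) and tripton (non-algal
particles) absorb short wavelengths preferentially, so the color ratios
shift from blue toward red as terrestrial loading increases downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLANCK_H",
    "SPEED_OF_LIGHT",
    "AVOGADRO",
    "Z1PCT_CONSTANT",
    "Waveband",
    "DEFAULT_BANDS",
    "SpectralProfile",
    "AttenuationResult",
    "ColorRatios",
    "integrate_quanta",
    "fit_kd",
    "penetration_depth_1pct",
    "photic_fraction",
    "color_ratio",
    "acdom_from_absorbance",
    "read_profiles_csv",
    "optics_table",
]

PLANCK_H = 6.62607015e-34   # J s
SPEED_OF_LIGHT = 299_792_458.0  # m s-1
AVOGADRO = 6.02214076e23    # mol-1
#: Conventional constant for the 1% light level; the field rounds -ln(0.01).
Z1PCT_CONSTANT = 4.6


@dataclass(frozen=True)
class Waveband:
    """A spectral waveband [a, b] in nm."""

    name: str
    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.a < self.b:
            raise ValueError(f"waveband {self.name}: require a < b")

    def mask(self, wavelengths: np.ndarray) -> np.ndarray:
        return (wavelengths >= self.a) & (wavelengths <= self.b)


#: Conventional wavebands: PAR plus the blue/green/red color bands.
DEFAULT_BANDS: dict[str, Waveband] = {
    "par": Waveband("par", 400.0, 700.0),
    "blue": Waveband("blue", 435.0, 500.0),
    "green": Waveband("green", 520.0, 565.0),
    "red": Waveband("red", 625.0, 740.0),
}


@dataclass
class SpectralProfile:
    """Depth x wavelength matrix of downwelling irradiance for one station.

    ``ed`` is in uW cm-2 nm-1, shape (n_depths, n_wavelengths); depths in m,
    strictly increasing; wavelengths in nm.
    """

    station: str
    depths: np.ndarray
    wavelengths: np.ndarray
    ed: np.ndarray
    dark_corrected: bool = True

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ed = np.asarray(self.ed, dtype=float)
        if self.depths.ndim != 1 or np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be 1-D and strictly increasing")
        if np.any(self.depths < 0):
            raise ValueError("depths must be >= 0")
        if self.ed.shape != (self.depths.size, self.wavelengths.size):
            raise ValueError(
                f"ed shape {self.ed.shape} != (n_depths, n_wavelengths) "
                f"({self.depths.size}, {self.wavelengths.size})"
            )
        if self.dark_corrected and np.any(self.ed < 0):
            raise ValueError("negative irradiance in a dark-corrected profile")


@dataclass
class AttenuationResult:
    """Fitted diffuse attenuation for one station and waveband."""

    band: str
    kd: float            # m-1; -slope of ln(E) vs z
    r2: float
    n_depths: int        # depths entering the regression
    n_dropped: int = 0   # nonpositive-irradiance depths excluded
    valid: bool = True   # False when the fitted slope is nonnegative

    @property
    def z1pct(self) -> float:
        """1% penetration depth (m), 4.6 / K_d."""
        return penetration_depth_1pct(self.kd)


@dataclass
class ColorRatios:
    """Relative penetration of wavebands.

    blue_red = K_d(red) / K_d(blue) = z1%(blue) / z1%(red): values > 1 mean
    blue light penetrates deeper than red.  ``valid`` is False when any
    constituent fit was flagged invalid.
    """

    blue_red: float
    green_red: float
    valid: bool = True


def integrate_quanta(
    profile: SpectralProfile, band: Waveband, depth_index: int
) -> float:
    """Photon flux in the band at one depth, in umol photons m-2 s-1.

    Integrates Ed(lambda) * lambda / (h c) over the band by the trapezoid
    rule on the measured wavelength grid, after converting irradiance from
    uW cm-2 nm-1 to W m-2 nm-1, then divides by Avogadro's number.  Band
    limits that fall between grid points are included as partial bins with
    Ed linearly interpolated, so the integral covers exactly [a, b].  A
    single isolated nonzero interior bin contributes
    Ed * lambda * dlambda / (h c N_A).
    """
    wl = profile.wavelengths
    if band.a < wl.min() or band.b > wl.max():
        raise ValueError(
            f"band {band.name} [{band.a}, {band.b}] outside measured range "
            f"[{wl.min()}, {wl.max()}]"
        )
    inner = (wl > band.a) & (wl < band.b)
    grid = np.concatenate(([band.a], wl[inner], [band.b]))
    ed_row = profile.ed[depth_index]
    ed = np.interp(grid, wl, ed_row)
    lam_m = grid * 1e-9                # nm -> m
    ed_si = ed * 1e-2                  # uW cm-2 nm-1 -> W m-2 nm-1
    # photons per nm: E * lambda / (h c); trapezoid over the nm grid
    photons = np.trapezoid(ed_si * lam_m / (PLANCK_H * SPEED_OF_LIGHT), grid)
    return photons / AVOGADRO * 1e6    # mol -> umol


def fit_kd(profile: SpectralProfile, band: Waveband) -> AttenuationResult:
    """Diffuse attenuation K_d for a band: -slope of ln(band quanta) vs depth.

    Depths whose integrated band irradiance is nonpositive are excluded from
    the regression and counted in ``n_dropped``.  A nonnegative slope (light
    not attenuating with depth) yields ``valid=False`` rather than a silent
    nonsensical K_d.
    """
    q = np.array(
        [integrate_quanta(profile, band, i) for i in range(profile.depths.size)]
    )
    usable = q > 0
    n_dropped = int((~usable).sum())
    if usable.sum() < 3:
        raise ValueError(
            f"band {band.name}: only {int(usable.sum())} depths with positive "
            "irradiance; need >= 3 for the log-linear fit"
        )
    z = profile.depths[usable]
    lnq = np.log(q[usable])
    res = stats.linregress(z, lnq)
    kd = -res.slope
    return AttenuationResult(
        band=band.name,
        kd=float(kd),
        r2=float(res.rvalue**2),
        n_depths=int(usable.sum()),
        n_dropped=n_dropped,
        valid=bool(kd > 0),
    )


def penetration_depth_1pct(kd: float) -> float:
    """Depth (m) where irradiance falls to 1% of surface: 4.6 / K_d."""
    if kd <= 0:
        raise ValueError("kd must be > 0")
    return Z1PCT_CONSTANT / kd


def photic_fraction(kd: float, water_depth_m: float) -> float:
    """Photic zone as a percent of the water column, capped at 100.

    (4.6 / K_d) / depth * 100; the cap expresses that the photic zone cannot
    exceed the water column — in shallow clear reaches light reaches bottom.
    """
    if kd <= 0 or water_depth_m <= 0:
        raise ValueError("kd and water depth must be > 0")
    return min(100.0, penetration_depth_1pct(kd) / water_depth_m * 100.0)


def color_ratio(
    att_blue: AttenuationResult,
    att_green: AttenuationResult,
    att_red: AttenuationResult,
) -> ColorRatios:
    """Blue/red and green/red penetration ratios from fitted attenuations."""
    valid = att_blue.valid and att_green.valid and att_red.valid
    if not valid:
        return ColorRatios(blue_red=np.nan, green_red=np.nan, valid=False)
    return ColorRatios(
        blue_red=att_red.kd / att_blue.kd,
        green_red=att_red.kd / att_green.kd,
        valid=True,
    )


def acdom_from_absorbance(
    a340: float, a690: float = 0.0, path_length_m: float = 0.01
) -> float:
    """CDOM absorption coefficient at 340 nm (m-1) from spectrophotometer absorbance.

    aCDOM340 = 2.303 * (A340 - A690) / l.  A690 is the near-infrared baseline
    (temperature-insensitive) subtracted to correct the UV reading; the
    default path length is the usual 10 mm quartz cell.
    """
    if path_length_m <= 0:
        raise ValueError("path length must be > 0")
    return 2.303 * (a340 - a690) / path_length_m


def read_profiles_csv(path) -> list[SpectralProfile]:
    """Read long-format profile CSV (station, depth_m, wavelength_nm, ed)."""
    df = pd.read_csv(path)
    required = {"station", "depth_m", "wavelength_nm", "ed"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    profiles = []
    for station, g in df.groupby("station", sort=True):
        mat = g.pivot_table(index="depth_m", columns="wavelength_nm", values="ed")
        profiles.append(
            SpectralProfile(
                station=str(station),
                depths=mat.index.to_numpy(),
                wavelengths=mat.columns.to_numpy(),
                ed=mat.to_numpy(),
            )
        )
    return profiles


def optics_table(
    profiles: list[SpectralProfile],
    bands: dict[str, Waveband] = DEFAULT_BANDS,
    water_depths: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-station optics summary: K_d, r2, z1%, color ratios, photic fraction.

    ``water_depths`` maps station id to water column depth (m); when absent
    the deepest measured depth of the profile is used.
    """
    rows = []
    for p in profiles:
        fits = {name: fit_kd(p, band) for name, band in bands.items()}
        ratios = color_ratio(fits["blue"], fits["green"], fits["red"])
        depth = (water_depths or {}).get(p.station, float(p.depths.max()))
        row: dict[str, object] = {"station": p.station, "water_depth_m": depth}
        for name, fit in fits.items():
            row[f"kd_{name}"] = fit.kd
            row[f"r2_{name}"] = fit.r2
            row[f"z1pct_{name}"] = fit.z1pct if fit.valid else np.nan
        row["blue_red"] = ratios.blue_red
        row["green_red"] = ratios.green_red
        row["photic_pct"] = (
            photic_fraction(fits["par"].kd, depth) if fits["par"].valid else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
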