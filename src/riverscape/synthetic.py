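"""Seeded synthetic rivers with the statistical structure the analysis assumes.

The generator builds a directional station network (a main stem of lateral
"lanes" sampled along transects, plus tributaries attaching at stations),
mixes conservative tracers downstream by discharge weighting, derives
band-specific diffuse attenuation from the mixed CDOM and tripton fields,
synthesises hyperspectral depth profiles by Beer-Lambert decay, and draws a
phytoplankton community whose cyanobacteria/eukaryote balance responds to
the underwater color ratio and to soluble reactive phosphorus (SRP).

Everything is driven by one integer seed through a single NumPy generator;
draw order is: (1) per-station profile noise in station order, (2) community
residuals in topological station order, (3) community count baselines.
Regenerating with the same config and seed reproduces every output
bit-identically.

The model is deliberately simple: mixing is conservative (discharge-weighted
means at confluences, optional first-order decay along edges), attenuation
is linear in the constituents, and the community response is log-linear.
It emulates the downstream structure of a tributary-fed river, not the
hydrodynamics of any particular one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .optics import DEFAULT_BANDS, SpectralProfile, Waveband

__all__ = [
    "Endmember",
    "Tributary",
    "BandOptics",
    "CommunityResponse",
    "RiverConfig",
    "SyntheticTruth",
    "SyntheticRiver",
    "demo_config",
    "generate_network",
    "mix_downstream",
    "spectral_kd",
    "generate_profiles",
    "generate_community",
    "simulate_river",
    "write_outputs",
]

WAVELENGTH_GRID = np.arange(351.0, 751.0, 3.0)  # nm, 3 nm instrument grid
DEPTH_STEP = 0.02  # m, profiler sampling interval


@dataclass(frozen=True)
class Endmember:
    """Source-water concentrations injected at an origin."""

    acdom340: float   # m-1
    tripton: float    # mg L-1
    srp: float        # ug L-1

    def __post_init__(self) -> None:
        if min(self.acdom340, self.tripton, self.srp) < 0:
            raise ValueError("endmember concentrations must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.acdom340, self.tripton, self.srp])


@dataclass(frozen=True)
class Tributary:
    """A tributary mouth: where it attaches and what it injects."""

    attachment_station: int
    discharge_m3s: float
    endmember: Endmember

    def __post_init__(self) -> None:
        if self.discharge_m3s <= 0:
            raise ValueError("tributary discharge must be > 0")


@dataclass(frozen=True)
class BandOptics:
    """Linear attenuation model for one waveband: kd = kw + s_cdom*aCDOM + s_trip*tripton."""

    kw: float       # m-1, clear-water baseline
    s_cdom: float   # m-1 per m-1 of aCDOM340
    s_trip: float   # m-1 per mg L-1 of tripton


@dataclass(frozen=True)
class CommunityResponse:
    """Log-linear response of the cyano/euk ratio to color and nutrients.

    ln(cyano/euk) = beta0 + beta_color * ln(blue/red) + beta_srp * ln(SRP) + eps,
    eps ~ N(0, noise_sd) either white or propagated downstream with AR(1)
    coefficient rho along graph edges.
    """

    beta0: float = 0.5
    beta_color: float = 1.2
    beta_srp: float = -0.4
    noise_sd: float = 0.15
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: Defaults emulate a CDOM-stained temperate river: blue attenuated most by
#: CDOM (s_cdom blue > green > red), tripton attenuating broadly.
DEFAULT_BAND_OPTICS: dict[str, BandOptics] = {
    "blue": BandOptics(kw=0.05, s_cdom=0.045, s_trip=0.30),
    "green": BandOptics(kw=0.04, s_cdom=0.020, s_trip=0.28),
    "red": BandOptics(kw=0.30, s_cdom=0.006, s_trip=0.25),
}


@dataclass
class RiverConfig:
    """Full specification of one synthetic river.

    The network is ``n_transects`` cross-river transects of
    ``stations_per_transect`` stations (lateral lanes); each lane is a
    downstream chain fed by the main-stem origin, and each tributary is a
    separate origin attached at one station.  Station indices are
    transect-major: station ``t * stations_per_transect + l`` is lane ``l``
    of transect ``t``.
    """

    n_transects: int = 16
    stations_per_transect: int = 3
    main_discharge_m3s: float = 8000.0
    main_endmember: Endmember = field(
        default_factory=lambda: Endmember(acdom340=2.0, tripton=1.0, srp=10.0)
    )
    tributaries: tuple[Tributary, ...] = ()
    band_optics: dict[str, BandOptics] = field(
        default_factory=lambda: dict(DEFAULT_BAND_OPTICS)
    )
    bands: dict[str, Waveband] = field(default_factory=lambda: dict(DEFAULT_BANDS))
    community: CommunityResponse = field(default_factory=CommunityResponse)
    ed0: float = 100.0            # uW cm-2 nm-1, flat surface spectrum
    profile_noise_sd: float = 0.05  # sd of ln Ed, multiplicative lognormal
    profile_depth_m: float = 4.0
    decay_per_edge: float = 0.0   # first-order loss fraction rate per edge
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transects < 1 or self.stations_per_transect < 1:
            raise ValueError("need at least one transect and one station per transect")
        if self.main_discharge_m3s <= 0:
            raise ValueError("main-stem discharge must be > 0")
        for name in ("blue", "green", "red"):
            if name not in self.band_optics:
                raise ValueError(f"band_optics must define '{name}'")
        if self.band_optics["blue"].s_cdom <= self.band_optics["red"].s_cdom:
            raise ValueError(
                "s_cdom(blue) must exceed s_cdom(red): CDOM absorbs blue preferentially"
            )
        if not 0.0 <= self.decay_per_edge < 1.0:
            raise ValueError("decay_per_edge must be in [0, 1)")
        n = self.n_stations
        for trib in self.tributaries:
            if not 0 <= trib.attachment_station < n:
                raise ValueError(
                    f"tributary attached to nonexistent station {trib.attachment_station}"
                )

    @property
    def n_stations(self) -> int:
        return self.n_transects * self.stations_per_transect

    def station_name(self, index: int) -> str:
        return f"s{index:03d}"


@dataclass
class SyntheticTruth:
    """Latent quantities the analysis tries to recover."""

    concentrations: pd.DataFrame     # station, acdom340, tripton, srp, discharge
    kd: pd.DataFrame                 # station, kd_blue, kd_green, kd_red
    color_ratios: pd.DataFrame       # station, blue_red, green_red
    response: CommunityResponse
    residuals: np.ndarray            # community eps per station
    seed: int


@dataclass
class SyntheticRiver:
    """One realised river: graph, station table, profiles, and latent truth."""

    config: RiverConfig
    graph: nx.DiGraph
    station_table: pd.DataFrame
    profiles: list[SpectralProfile]
    truth: SyntheticTruth


def demo_config(
    seed: int = 0,
    n_transects: int = 16,
    stations_per_transect: int = 3,
    rho: float = 0.0,
    noise_sd: float = 0.15,
) -> RiverConfig:
    """A tributary-fed river with contrasting source waters.

    Five tributaries attach along the reach, alternating shore lanes:
    two CDOM-stained brownwater rivers, two turbid nutrient-rich
    agricultural rivers, and one clear oligotrophic one.  This produces
    downstream gradients and lateral contrasts in color ratio and SRP that
    are strong relative to the community noise, the regime the analysis is
    meant for.
    """
    lanes = stations_per_transect

    def at(frac: float, lane: int) -> int:
        t = min(n_transects - 1, max(0, int(round(frac * (n_transects - 1)))))
        return t * lanes + min(lane, lanes - 1)

    tribs = (
        Tributary(at(0.15, 0), 900.0, Endmember(acdom340=28.0, tripton=3.0, srp=22.0)),
        Tributary(at(0.30, lanes - 1), 500.0, Endmember(acdom340=6.0, tripton=14.0, srp=55.0)),
        Tributary(at(0.50, 0), 700.0, Endmember(acdom340=22.0, tripton=2.0, srp=12.0)),
        Tributary(at(0.65, lanes - 1), 400.0, Endmember(acdom340=4.0, tripton=10.0, srp=70.0)),
        Tributary(at(0.82, 0), 300.0, Endmember(acdom340=1.0, tripton=0.5, srp=4.0)),
    )
    return RiverConfig(
        n_transects=n_transects,
        stations_per_transect=stations_per_transect,
        tributaries=tribs,
        community=CommunityResponse(
            beta0=0.5, beta_color=1.2, beta_srp=-0.4, noise_sd=noise_sd, rho=rho
        ),
        seed=seed,
    )


def generate_network(config: RiverConfig) -> nx.DiGraph:
    """Build the directional station graph.

    Nodes carry ``kind`` ("origin" or "station"); origins carry ``discharge``
    and ``endmember``.  Edges point downstream only and carry ``weight`` 1.
    One virtual origin sits upstream of the main-stem head (feeding every
    lane) and one upstream of each tributary mouth.
    """
    g = nx.DiGraph()
    lanes = config.stations_per_transect
    for i in range(config.n_stations):
        g.add_node(
            config.station_name(i),
            kind="station",
            transect=i // lanes,
            lane=i % lanes,
        )
    g.add_node(
        "o_main",
        kind="origin",
        discharge=config.main_discharge_m3s,
        endmember=config.main_endmember.as_array(),
    )
    for lane in range(lanes):
        g.add_edge("o_main", config.station_name(lane), weight=1.0)
    for t in range(config.n_transects - 1):
        for lane in range(lanes):
            g.add_edge(
                config.station_name(t * lanes + lane),
                config.station_name((t + 1) * lanes + lane),
                weight=1.0,
            )
    for j, trib in enumerate(config.tributaries):
        origin = f"o_trib{j:02d}"
        g.add_node(
            origin,
            kind="origin",
            discharge=trib.discharge_m3s,
            endmember=trib.endmember.as_array(),
        )
        g.add_edge(origin, config.station_name(trib.attachment_station), weight=1.0)
    if not nx.is_directed_acyclic_graph(g):  # defensive; construction is acyclic
        raise ValueError("cycle detected in river graph")
    origins = [n for n, d in g.nodes(data=True) if d["kind"] == "origin"]
    reachable: set[str] = set()
    for o in origins:
        reachable |= nx.descendants(g, o)
    unreachable = [
        n for n, d in g.nodes(data=True)
        if d["kind"] == "station" and n not in reachable
    ]
    if unreachable:
        raise ValueError(f"stations unreachable from any origin: {unreachable}")
    return g


def mix_downstream(graph: nx.DiGraph, config: RiverConfig) -> pd.DataFrame:
    """Propagate concentrations downstream by discharge-weighted mixing.

    At each confluence the concentration is the discharge-weighted mean of
    the inflows (conservative mixing: mass flux concentration x discharge is
    conserved).  An origin feeding several lane heads splits its discharge
    equally among them.  With ``decay_per_edge`` > 0, aCDOM and tripton lose
    that fraction along every edge (first-order loss); SRP stays conservative.
    """
    conc: dict[str, np.ndarray] = {}
    outflow: dict[str, float] = {}
    for node in nx.topological_sort(graph):
        data = graph.nodes[node]
        if data["kind"] == "origin":
            conc[node] = np.asarray(data["endmember"], dtype=float)
            outflow[node] = float(data["discharge"])
            continue
        q_in = 0.0
        flux = np.zeros(3)
        for parent in graph.predecessors(node):
            q_edge = outflow[parent] / graph.out_degree(parent)
            c = conc[parent].copy()
            if config.decay_per_edge > 0:
                c[:2] *= 1.0 - config.decay_per_edge  # aCDOM, tripton only
            q_in += q_edge
            flux += q_edge * c
        if q_in <= 0:
            raise ZeroDivisionError(f"zero total discharge at station {node}")
        conc[node] = flux / q_in
        outflow[node] = q_in
    stations = sorted(
        n for n, d in graph.nodes(data=True) if d["kind"] == "station"
    )
    return pd.DataFrame(
        {
            "station": stations,
            "acdom340": [conc[s][0] for s in stations],
            "tripton": [conc[s][1] for s in stations],
            "srp": [conc[s][2] for s in stations],
            "discharge": [outflow[s] for s in stations],
        }
    )


def band_kd(concentrations: pd.DataFrame, config: RiverConfig) -> pd.DataFrame:
    """True diffuse attenuation per configured band at every station."""
    out = {"station": concentrations["station"].to_numpy()}
    for name, bo in config.band_optics.items():
        kd = (
            bo.kw
            + bo.s_cdom * concentrations["acdom340"].to_numpy()
            + bo.s_trip * concentrations["tripton"].to_numpy()
        )
        if np.any(kd <= 0):
            raise ValueError(f"nonpositive K_d for band '{name}' from config")
        out[f"kd_{name}"] = kd
    return pd.DataFrame(out)


def spectral_kd(kd_bands: dict[str, float], config: RiverConfig) -> np.ndarray:
    """Expand band K_d values to the full wavelength grid.

    Piecewise constant: every wavelength takes the K_d of the nearest color
    band, with steps at the midpoints of the gaps between bands.  Constancy
    within (and right up to the edges of) each band means a log-linear fit
    over the band recovers its K_d exactly at zero noise; the step structure
    is a deliberate simplification of a smooth attenuation spectrum.
    """
    wl = WAVELENGTH_GRID
    # order bands by lower edge; only the three color bands define the curve
    bands = sorted(
        ((config.bands[name], kd_bands[name]) for name in ("blue", "green", "red")),
        key=lambda p: p[0].a,
    )
    kd = np.full(wl.size, bands[0][1])
    for (prev, _), (band, value) in zip(bands, bands[1:]):
        cut = 0.5 * (prev.b + band.a)  # midpoint of the spectral gap
        kd[wl > cut] = value
    return kd


def generate_profiles(
    concentrations: pd.DataFrame, config: RiverConfig, rng: np.random.Generator
) -> tuple[list[SpectralProfile], pd.DataFrame]:
    """Synthesise Ed(lambda, z) profiles from latent concentrations.

    Ed(lambda, z) = Ed0 * exp(-K_d(lambda) * z), with multiplicative
    lognormal noise of configured log-sd, depths on a 0.02 m grid and
    wavelengths 351-750 nm at 3 nm.  Returns the profiles and the table of
    true band K_d used to build them.
    """
    kd_table = band_kd(concentrations, config)
    depths = np.arange(0.0, config.profile_depth_m + DEPTH_STEP / 2, DEPTH_STEP)
    profiles = []
    for _, row in kd_table.iterrows():
        kd_wl = spectral_kd(
            {b: row[f"kd_{b}"] for b in ("blue", "green", "red")}, config
        )
        ed = config.ed0 * np.exp(-np.outer(depths, kd_wl))
        if config.profile_noise_sd > 0:
            ed = ed * np.exp(
                config.profile_noise_sd * rng.standard_normal(ed.shape)
            )
        profiles.append(
            SpectralProfile(
                station=row["station"],
                depths=depths,
                wavelengths=WAVELENGTH_GRID,
                ed=ed,
            )
        )
    return profiles, kd_table


def true_color_ratios(kd_table: pd.DataFrame) -> pd.DataFrame:
    """Color ratios from the latent band attenuations (K_d(red)/K_d(color))."""
    return pd.DataFrame(
        {
            "station": kd_table["station"],
            "blue_red": kd_table["kd_red"] / kd_table["kd_blue"],
            "green_red": kd_table["kd_red"] / kd_table["kd_green"],
        }
    )


def _graph_residuals(
    graph: nx.DiGraph, stations: list[str], response: CommunityResponse,
    rng: np.random.Generator,
) -> np.ndarray:
    """Community residuals, white or AR(1)-propagated along graph edges.

    With rho > 0 a station inherits rho times the mean residual of its
    upstream station parents plus an innovation scaled so the marginal
    variance stays noise_sd^2 on a chain.
    """
    sd, rho = response.noise_sd, response.rho
    eps: dict[str, float] = {}
    innovations = {s: rng.normal(0.0, 1.0) for s in stations}
    for node in nx.topological_sort(graph):
        if graph.nodes[node]["kind"] != "station":
            continue
        parents = [
            p for p in graph.predecessors(node)
            if graph.nodes[p]["kind"] == "station"
        ]
        if rho == 0.0 or not parents:
            eps[node] = sd * innovations[node]
        else:
            inherited = float(np.mean([eps[p] for p in parents]))
            eps[node] = rho * inherited + sd * np.sqrt(1 - rho**2) * innovations[node]
    return np.array([eps[s] for s in stations])


def generate_community(
    concentrations: pd.DataFrame,
    color_ratios: pd.DataFrame,
    config: RiverConfig,
    rng: np.random.Generator,
    graph: nx.DiGraph | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw phytoplankton counts responding to color ratio and SRP.

    ln(cyano/euk) = beta0 + beta_color ln(blue/red) + beta_srp ln(SRP) + eps.
    Total eukaryote density is a lognormal baseline; the cyanobacteria total
    follows from the ratio; pico/nano splits and a Chl a proxy are fixed
    allometric fractions with lognormal scatter.  Returns the station table
    and the residual vector eps (part of the latent truth).
    """
    resp = config.community
    srp = concentrations["srp"].to_numpy()
    ratio = color_ratios["blue_red"].to_numpy()
    if np.any(srp <= 0):
        raise ValueError("nonpositive SRP: cannot take log")
    if np.any(ratio <= 0):
        raise ValueError("nonpositive color ratio: cannot take log")
    stations = list(concentrations["station"])
    if resp.rho > 0 and graph is None:
        raise ValueError("graph required for spatially correlated residuals")
    if graph is not None:
        eps = _graph_residuals(graph, stations, resp, rng)
    else:
        eps = resp.noise_sd * rng.standard_normal(len(stations))
    ln_ratio = resp.beta0 + resp.beta_color * np.log(ratio) + resp.beta_srp * np.log(srp) + eps
    cyano_euk = np.exp(ln_ratio)
    # baselines: ~2e4 euk cells/mL, scattered lognormally
    euk_total = np.exp(rng.normal(np.log(2.0e4), 0.2, len(stations)))
    cyano_total = cyano_euk * euk_total
    pico_frac_cyano, pico_frac_euk = 0.81, 0.35
    df = pd.DataFrame(
        {
            "station": stations,
            "picocyano": pico_frac_cyano * cyano_total,
            "nanocyano": (1 - pico_frac_cyano) * cyano_total,
            "picoeuk": pico_frac_euk * euk_total,
            "nanoeuk": (1 - pico_frac_euk) * euk_total,
            "cyano_euk": cyano_euk,
        }
    )
    # Chl a proxy: nano cells carry far more pigment per cell than pico cells
    df["chla"] = (
        2e-4 * (df["nanocyano"] + df["nanoeuk"])
        + 2e-5 * (df["picocyano"] + df["picoeuk"])
    ) * np.exp(rng.normal(0.0, 0.1, len(stations)))
    return df, eps


def simulate_river(config: RiverConfig) -> SyntheticRiver:
    """Run the full generator: network, mixing, profiles, community."""
    rng = np.random.default_rng(config.seed)
    graph = generate_network(config)
    conc = mix_downstream(graph, config)
    profiles, kd_table = generate_profiles(conc, config, rng)
    ratios = true_color_ratios(kd_table)
    community, eps = generate_community(conc, ratios, config, rng, graph=graph)
    lanes = config.stations_per_transect
    idx = np.arange(config.n_stations)
    station_table = (
        conc.merge(ratios, on="station").merge(community, on="station")
    )
    station_table.insert(1, "transect", idx // lanes)
    station_table.insert(2, "lane", idx % lanes)
    truth = SyntheticTruth(
        concentrations=conc,
        kd=kd_table,
        color_ratios=ratios,
        response=config.community,
        residuals=eps,
        seed=config.seed,
    )
    return SyntheticRiver(
        config=config,
        graph=graph,
        station_table=station_table,
        profiles=profiles,
        truth=truth,
    )


def write_outputs(river: SyntheticRiver, outdir: str | Path) -> dict[str, Path]:
    """Write station CSV, long-format profiles CSV, edge-list TSV, GraphML, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stations": outdir / "stations.csv",
        "profiles": outdir / "profiles.csv",
        "edges": outdir / "graph_edges.tsv",
        "graphml": outdir / "graph.graphml",
        "truth": outdir / "truth.json",
    }
    river.station_table.to_csv(paths["stations"], index=False)
    frames = []
    for p in river.profiles:
        nz, nw = p.depths.size, p.wavelengths.size
        frames.append(
            pd.DataFrame(
                {
                    "station": np.repeat(p.station, nz * nw),
                    "depth_m": np.repeat(p.depths, nw),
                    "wavelength_nm": np.tile(p.wavelengths, nz),
                    "ed": p.ed.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(paths["profiles"], index=False)
    with open(paths["edges"], "w") as fh:
        for u, v, d in river.graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{d.get('weight', 1.0)}\n")
    graphml = river.graph.copy()
    for _, data in graphml.nodes(data=True):  # GraphML cannot store arrays
        if "endmember" in data:
            data["endmember"] = json.dumps(list(np.asarray(data["endmember"])))
    nx.write_graphml(graphml, paths["graphml"])
    truth_payload = {
        "seed": river.truth.seed,
        "response": asdict(river.truth.response),
        "kd": river.truth.kd.to_dict(orient="list"),
        "concentrations": river.truth.concentrations.to_dict(orient="list"),
        "color_ratios": river.truth.color_ratios.to_dict(orient="list"),
        "residuals": river.truth.residuals.tolist(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_payload, fh, indent=1)
    return paths
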