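"""Monte-Carlo simulator of MALDI ion packets probed by a sheet laser.

Generates ensembles of ions whose ejection time t_E and initial velocity v0
are drawn from per-species distributions, propagates them through the
extraction gap with the closed-form kinematics, removes (photodissociates)
the ions found inside a 1-mm probe slab at the probe delay, and renders
shot-averaged TOF spectra.  The output reproduces the phenomenology the
inverse analysis consumes: a smooth baseline peak per species, and probed
spectra with a missing segment that marches across the peak as the probe
delay grows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np

from .constants import MM, NS
from .kinematics import (
    InstrumentConfig,
    IonSpecies,
    fragment_arrival_arrays,
    propagate_distance,
    time_of_flight,
    velocity_at,
)

__all__ = [
    "PlumeModel",
    "ProbeEvent",
    "Spectrum",
    "ScenarioGrid",
    "IonEnsemble",
    "DissociatedIons",
    "ScenarioArchive",
    "sample_ions",
    "positions_at",
    "apply_probe",
    "render_spectrum",
    "generate_scenario",
    "DEFAULT_FRAGMENT_MASSES_U",
]

#: Generic low-mass CnHm+ fragment masses (u) used to render probe-induced
#: fragment signals; cosmetic only, excluded from all inference.
DEFAULT_FRAGMENT_MASSES_U = (27.0, 39.0, 51.0, 63.0, 77.0)

TE_SHAPES = ("gaussian_truncated_at_zero", "lognormal")


@dataclass(frozen=True)
class PlumeModel:
    """Statistical model of one species' ion packet at the source.

    t_E is the per-ion ejection delay after the MALDI pulse; v0 the initial
    axial velocity.  Both default shapes are gaussians truncated at zero
    (negative draws redrawn, not clipped).
    """

    species: IonSpecies
    tE_mean: float  # s
    tE_sd: float  # s
    v0_mean: float = 500.0  # m/s
    v0_sd: float = 150.0  # m/s
    ions_per_shot: int = 5000
    tE_shape: str = "gaussian_truncated_at_zero"

    def __post_init__(self) -> None:
        if self.tE_mean < 0 or self.tE_sd < 0:
            raise ValueError("tE_mean and tE_sd must be >= 0")
        if self.v0_mean < 0 or self.v0_sd < 0:
            raise ValueError("v0_mean and v0_sd must be >= 0")
        if self.ions_per_shot < 1:
            raise ValueError("ions_per_shot must be >= 1")
        if self.tE_shape not in TE_SHAPES:
            raise ValueError(f"tE_shape must be one of {TE_SHAPES}")


@dataclass(frozen=True)
class ProbeEvent:
    """One firing of the sheet probe: delay, slab extent, removal probability."""

    delta_t: float  # s, delay from the MALDI pulse centre
    slab_low: float  # m
    slab_high: float  # m
    dissociation_prob: float = 1.0
    jitter_sd: float = 0.0  # s, optional per-shot gaussian timing jitter

    def __post_init__(self) -> None:
        if self.slab_high <= self.slab_low:
            raise ValueError("slab_high must exceed slab_low")
        if not 0.0 <= self.dissociation_prob <= 1.0:
            raise ValueError("dissociation_prob must be in [0, 1]")

    @property
    def thickness(self) -> float:
        return self.slab_high - self.slab_low


@dataclass
class IonEnsemble:
    """Per-shot draws of (t_E, v0); arrays shaped (n_shots, ions_per_shot)."""

    t_e: np.ndarray
    v0: np.ndarray

    def __post_init__(self) -> None:
        if self.t_e.shape != self.v0.shape:
            raise ValueError("t_e and v0 must share a shape")

    @property
    def n_shots(self) -> int:
        return self.t_e.shape[0]

    @property
    def n_ions(self) -> int:
        return self.t_e.size


@dataclass
class DissociatedIons:
    """Ions removed by the probe, with their state at the probe delay."""

    t_e: np.ndarray
    v0: np.ndarray
    shot: np.ndarray  # shot index of each removed ion
    position: np.ndarray  # m, at the probe delay
    velocity: np.ndarray  # m/s, at the probe delay
    time: float  # s, the probe delay

    @property
    def n_ions(self) -> int:
        return self.t_e.size


@dataclass
class Spectrum:
    """A shot-averaged TOF histogram with provenance metadata."""

    bin_edges: np.ndarray  # s, uniform, len = n_bins + 1
    counts: np.ndarray  # mean ions per bin per shot, >= 0
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("len(counts) must be len(bin_edges) - 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def total(self) -> float:
        return float(self.counts.sum())

    # -- CSV dialect: `tof_ns,intensity`, one row per bin centre, 6 s.f.;
    #    sidecar JSON <name>.json carries metadata (instrument, scenario, seed).
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("tof_ns,intensity\n")
            for t, c in zip(self.bin_centres, self.counts):
                fh.write(f"{t / NS:.6g},{c:.6g}\n")
        sidecar = path.with_suffix(path.suffix + ".json")
        with sidecar.open("w", encoding="utf-8") as fh:
            json.dump(self.metadata, fh, indent=1, sort_keys=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Spectrum":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        centres = data[:, 0] * NS
        counts = data[:, 1]
        width = float(np.median(np.diff(centres))) if len(centres) > 1 else 10e-9
        edges = np.concatenate([centres - width / 2, [centres[-1] + width / 2]])
        sidecar = path.with_suffix(path.suffix + ".json")
        metadata = {}
        if sidecar.exists():
            metadata = json.loads(sidecar.read_text(encoding="utf-8"))
        return cls(bin_edges=edges, counts=counts, metadata=metadata)


@dataclass(frozen=True)
class ScenarioGrid:
    """The measurement design: probe slabs x delays x voltages."""

    slabs: tuple  # of (z_low, z_high) in m
    delays: tuple  # s, sorted ascending
    voltages: tuple  # V
    shots_per_spectrum: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.slabs or not self.delays or not self.voltages:
            raise ValueError("slabs, delays and voltages must be non-empty")
        if list(self.delays) != sorted(self.delays):
            raise ValueError("delays must be sorted ascending")
        if self.shots_per_spectrum < 1:
            raise ValueError("shots_per_spectrum must be >= 1")

    @classmethod
    def paper_default(cls, seed: int = 0, shots_per_spectrum: int = 20) -> "ScenarioGrid":
        """The published design: 4 slabs (0.6–4.6 mm, 1 mm steps), delays
        0–500 ns in 50-ns steps, voltages +3.5/+4.5/+5.5 kV."""
        slabs = tuple((0.6e-3 + i * 1e-3, 1.6e-3 + i * 1e-3) for i in range(4))
        delays = tuple(i * 50e-9 for i in range(11))
        return cls(
            slabs=slabs,
            delays=delays,
            voltages=(3500.0, 4500.0, 5500.0),
            shots_per_spectrum=shots_per_spectrum,
            seed=seed,
        )


def sample_ions(model: PlumeModel, n_shots: int, seed) -> IonEnsemble:
    """Draw a per-shot (t_E, v0) ensemble; deterministic given *seed*.

    Truncated-gaussian draws are redrawn (not clipped) while negative, so the
    resulting distribution is the gaussian conditioned on positivity.
    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    rng = np.random.default_rng(seed)
    shape = (n_shots, model.ions_per_shot)
    if model.tE_shape == "lognormal":
        t_e = _lognormal(rng, model.tE_mean, model.tE_sd, shape)
    else:
        t_e = _truncated_gaussian(rng, model.tE_mean, model.tE_sd, shape)
    v0 = _truncated_gaussian(rng, model.v0_mean, model.v0_sd, shape)
    return IonEnsemble(t_e=t_e, v0=v0)


def _truncated_gaussian(rng, mean, sd, shape) -> np.ndarray:
    if sd == 0:
        return np.full(shape, float(mean))
    out = rng.normal(mean, sd, size=shape)
    bad = out < 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < 0
    return out


def _lognormal(rng, mean, sd, shape) -> np.ndarray:
    if mean <= 0:
        raise ValueError("lognormal requires mean > 0")
    if sd == 0:
        return np.full(shape, float(mean))
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=shape)


def positions_at(
    ensemble: IonEnsemble, species: IonSpecies, field: float, delta_t: float
) -> np.ndarray:
    """Per-ion positions at delay ``delta_t`` (0 for not-yet-ejected ions)."""
    return propagate_distance(ensemble.t_e, ensemble.v0, species, field, delta_t)


def apply_probe(
    ensemble: IonEnsemble,
    species: IonSpecies,
    field: float,
    probe: ProbeEvent,
    seed,
) -> tuple[IonEnsemble, DissociatedIons]:
    """Partition the ensemble into probe survivors and dissociated ions.

    Each ion whose position at the probe delay falls inside
    ``[slab_low, slab_high)`` is removed with probability
    ``dissociation_prob``; removed ions carry their kinematic state at the
    delay so fragments can be rendered.  The partition is exhaustive and
    disjoint.  Survivors keep the (n_shots, ions_per_shot) layout as a masked
    flat view grouped by shot via ``shot`` indices on the dissociated side.
    """
    rng = np.random.default_rng(seed)
    n_shots, n_per = ensemble.t_e.shape
    delta_t = np.full((n_shots, 1), probe.delta_t)
    if probe.jitter_sd > 0:
        delta_t = delta_t + rng.normal(0.0, probe.jitter_sd, size=(n_shots, 1))
        delta_t = np.maximum(delta_t, 0.0)
    pos = propagate_distance(ensemble.t_e, ensemble.v0, species, field, delta_t)
    in_slab = (pos >= probe.slab_low) & (pos < probe.slab_high)
    if probe.dissociation_prob >= 1.0:
        removed = in_slab
    elif probe.dissociation_prob <= 0.0:
        removed = np.zeros_like(in_slab)
    else:
        removed = in_slab & (rng.random(in_slab.shape) < probe.dissociation_prob)

    shot_idx, ion_idx = np.nonzero(removed)
    vel = velocity_at(ensemble.t_e, ensemble.v0, species, field, delta_t)
    dissociated = DissociatedIons(
        t_e=ensemble.t_e[removed],
        v0=ensemble.v0[removed],
        shot=shot_idx,
        position=pos[removed],
        velocity=vel[removed],
        time=probe.delta_t,
    )
    keep = ~removed
    survivors = _MaskedEnsemble(
        t_e=ensemble.t_e, v0=ensemble.v0, keep=keep
    )
    return survivors, dissociated


@dataclass
class _MaskedEnsemble(IonEnsemble):
    """An IonEnsemble with a boolean keep-mask (probe survivors)."""

    keep: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.keep is None:
            self.keep = np.ones_like(self.t_e, dtype=bool)

    @property
    def n_ions(self) -> int:
        return int(self.keep.sum())


def _ensemble_mask(ensemble: IonEnsemble) -> np.ndarray:
    if isinstance(ensemble, _MaskedEnsemble):
        return ensemble.keep
    return np.ones_like(ensemble.t_e, dtype=bool)


def default_bin_edges(
    instrument: InstrumentConfig,
    species_list,
    te_max: float = 400e-9,
    v0_max: float = 2000.0,
    include_fragments: bool = True,
    fragment_masses_u=DEFAULT_FRAGMENT_MASSES_U,
) -> np.ndarray:
    """Uniform bin edges covering every plausible arrival for *species_list*.

    The range spans from 80% of the lightest fragment's minimum flight time to
    the heaviest species' flight time at (te_max, v0 = 0), padded 10%.
    """
    lo_masses = list(fragment_masses_u) if include_fragments else []
    lo_masses += [sp.mass_u for sp in species_list]
    fastest = IonSpecies("fastest", min(lo_masses))
    slowest = max(species_list, key=lambda sp: sp.mass_u / sp.charge)
    t_lo = 0.8 * time_of_flight(0.0, v0_max, fastest, instrument)
    t_hi = 1.1 * time_of_flight(te_max, 0.0, slowest, instrument)
    n_bins = int(np.ceil((t_hi - t_lo) / instrument.bin_width))
    return t_lo + instrument.bin_width * np.arange(n_bins + 1)


def render_spectrum(
    survivors,
    dissociated,
    instrument: InstrumentConfig,
    bin_edges: np.ndarray | None = None,
    fragments_on: bool = True,
    shot_noise: bool = False,
    seed=None,
    fragment_masses_u=DEFAULT_FRAGMENT_MASSES_U,
    metadata: dict | None = None,
    _tof_cache: dict | None = None,
) -> Spectrum:
    """Histogram detector arrivals into a shot-averaged TOF spectrum.

    Parameters
    ----------
    survivors:
        List of ``(IonEnsemble, IonSpecies)`` pairs; all species are merged
        into one spectrum, as on the real instrument.
    dissociated:
        List of ``(DissociatedIons, IonSpecies)`` pairs; when *fragments_on*
        each removed ion is re-rendered as one low-mass CnHm+ fragment, so the
        total ion count is conserved: baseline = survivors + fragments.
    shot_noise:
        If true, each shot's integer bin counts are replaced by Poisson draws
        before averaging over shots (approximating ~20-shot signal averaging
        of a counting detector).

    Raises
    ------
    ValueError
        If any arrival falls outside ``bin_edges`` (the offending times are
        listed).
    """
    rng = np.random.default_rng(seed)
    species_list = [sp for _, sp in survivors]
    if bin_edges is None:
        bin_edges = default_bin_edges(
            instrument, species_list, include_fragments=fragments_on,
            fragment_masses_u=fragment_masses_u,
        )
    arrivals = []  # (times, shot_index) pairs
    n_shots = max((ens.n_shots for ens, _ in survivors), default=1)
    for ens, sp in survivors:
        keep = _ensemble_mask(ens)
        if _tof_cache is not None and id(ens) in _tof_cache:
            tof = _tof_cache[id(ens)]
        else:
            tof = time_of_flight(ens.t_e, ens.v0, sp, instrument)
            if _tof_cache is not None:
                _tof_cache[id(ens)] = tof
        shot = np.broadcast_to(
            np.arange(ens.n_shots)[:, None], ens.t_e.shape
        )
        arrivals.append((tof[keep], shot[keep]))
    if fragments_on:
        for dis, parent in dissociated:
            if dis.n_ions == 0:
                continue
            frag_mass = rng.choice(fragment_masses_u, size=dis.n_ions)
            times = np.empty(dis.n_ions)
            for m in np.unique(frag_mass):
                sel = frag_mass == m
                frag = IonSpecies(f"CnHm+({m:.0f})", float(m))
                times[sel] = fragment_arrival_arrays(
                    dis.position[sel], dis.velocity[sel], dis.time, frag, instrument
                )
            arrivals.append((times, dis.shot))

    all_times = np.concatenate([t for t, _ in arrivals]) if arrivals else np.empty(0)
    out_of_range = (all_times < bin_edges[0]) | (all_times >= bin_edges[-1])
    if np.any(out_of_range):
        bad = np.sort(all_times[out_of_range])
        raise ValueError(
            f"{bad.size} arrival(s) outside bin range "
            f"[{bin_edges[0]:.3e}, {bin_edges[-1]:.3e}] s; first offenders: "
            f"{[f'{t:.4e}' for t in bad[:5]]}"
        )

    if shot_noise:
        counts = np.zeros(len(bin_edges) - 1)
        all_shots = np.concatenate([s for _, s in arrivals])
        for k in range(n_shots):
            shot_counts, _ = np.histogram(all_times[all_shots == k], bins=bin_edges)
            counts += rng.poisson(shot_counts)
        counts = counts / n_shots
    else:
        counts, _ = np.histogram(all_times, bins=bin_edges)
        counts = counts / n_shots

    meta = dict(metadata or {})
    meta.setdefault("n_shots", int(n_shots))
    meta.setdefault("bin_width_ns", instrument.bin_width / NS)
    return Spectrum(bin_edges=np.asarray(bin_edges, float), counts=counts, metadata=meta)


@dataclass
class ScenarioArchive:
    """Output of :func:`generate_scenario`: spectra keyed by grid cell.

    ``baselines[voltage]`` is the unprobed spectrum; ``probed[(voltage,
    slab, delay)]`` the probed one.  ``provenance`` records grid, models,
    instrument template and seed so an archive regenerates bitwise.
    """

    baselines: dict
    probed: dict
    instruments: dict  # voltage -> InstrumentConfig
    provenance: dict

    def save(self, directory: str | Path) -> None:
        """Write the archive as per-voltage directories of spectrum CSVs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "provenance.json").write_text(
            json.dumps(self.provenance, indent=1, sort_keys=True), encoding="utf-8"
        )
        for voltage, spec in self.baselines.items():
            vdir = directory / f"{voltage / 1e3:g}kV"
            vdir.mkdir(exist_ok=True)
            spec.to_csv(vdir / "baseline.csv")
        for (voltage, slab, delay), spec in self.probed.items():
            vdir = directory / f"{voltage / 1e3:g}kV"
            name = (
                f"probe_z{slab[0] / MM:g}-{slab[1] / MM:g}mm_dt{delay / NS:g}ns.csv"
            )
            spec.to_csv(vdir / name)

    @classmethod
    def load(cls, directory: str | Path) -> "ScenarioArchive":
        directory = Path(directory)
        prov_path = directory / "provenance.json"
        provenance = (
            json.loads(prov_path.read_text(encoding="utf-8"))
            if prov_path.exists()
            else {}
        )
        baselines: dict = {}
        probed: dict = {}
        instruments: dict = {}
        for vdir in sorted(directory.glob("*kV")):
            voltage = float(vdir.name[:-2]) * 1e3
            base = vdir / "baseline.csv"
            if not base.exists():
                raise FileNotFoundError(f"missing baseline for {vdir.name}: {base}")
            baselines[voltage] = Spectrum.from_csv(base)
            inst_meta = baselines[voltage].metadata.get("instrument")
            if inst_meta:
                instruments[voltage] = InstrumentConfig(**inst_meta)
            for f in sorted(vdir.glob("probe_z*mm_dt*ns.csv")):
                stem = f.stem  # probe_z{lo}-{hi}mm_dt{ns}ns
                zpart, dtpart = stem[len("probe_z"):].split("mm_dt")
                lo, hi = (float(x) * MM for x in zpart.split("-"))
                delay = float(dtpart[:-2]) * NS
                probed[(voltage, (lo, hi), delay)] = Spectrum.from_csv(f)
        return cls(
            baselines=baselines,
            probed=probed,
            instruments=instruments,
            provenance=provenance,
        )


def generate_scenario(
    grid: ScenarioGrid,
    models,
    instrument_template: InstrumentConfig,
    fragments_on: bool = True,
    shot_noise: bool = True,
    dissociation_prob: float = 1.0,
    jitter_sd: float = 0.0,
) -> ScenarioArchive:
    """Run the full measurement design: one baseline per voltage plus one
    probed spectrum per (slab, delay, voltage) cell.

    Per voltage and species a single ensemble of ``shots_per_spectrum`` shots
    is drawn and reused across every probe cell, so probed spectra are
    bin-wise dominated by their baseline when noise is off.  Fully
    reproducible from ``grid.seed``.
    """
    root_ss = np.random.SeedSequence(grid.seed)
    archive_base: dict = {}
    archive_probe: dict = {}
    instruments: dict = {}
    for v_idx, voltage in enumerate(grid.voltages):
        instrument = replace(instrument_template, voltage=voltage, field=0.0)
        instruments[voltage] = instrument
        v_ss = np.random.SeedSequence(entropy=grid.seed, spawn_key=(v_idx,))
        ens_seeds = v_ss.spawn(len(models) + 1)
        ensembles = [
            sample_ions(m, grid.shots_per_spectrum, ens_seeds[i])
            for i, m in enumerate(models)
        ]
        cell_rng_root = ens_seeds[-1]
        species_list = [m.species for m in models]
        bin_edges = default_bin_edges(instrument, species_list)
        tof_cache: dict = {}
        inst_meta = {
            "voltage": instrument.voltage,
            "gap": instrument.gap,
            "drift_length": instrument.drift_length,
            "bin_width": instrument.bin_width,
        }

        pairs = list(zip(ensembles, species_list))
        base_meta = {
            "instrument": inst_meta,
            "scenario": {"voltage_V": voltage, "probe": None},
            "seed": grid.seed,
        }
        archive_base[voltage] = render_spectrum(
            pairs,
            [],
            instrument,
            bin_edges=bin_edges,
            fragments_on=fragments_on,
            shot_noise=shot_noise,
            seed=np.random.SeedSequence(entropy=grid.seed, spawn_key=(v_idx, 99991)),
            metadata=base_meta,
            _tof_cache=tof_cache,
        )

        cell_seeds = cell_rng_root.spawn(len(grid.slabs) * len(grid.delays))
        k = 0
        for slab in grid.slabs:
            for delay in grid.delays:
                probe = ProbeEvent(
                    delta_t=delay,
                    slab_low=slab[0],
                    slab_high=slab[1],
                    dissociation_prob=dissociation_prob,
                    jitter_sd=jitter_sd,
                )
                cell_ss = cell_seeds[k]
                k += 1
                sub = cell_ss.spawn(len(pairs) + 1)
                cell_survivors = []
                cell_dissociated = []
                for i, (ens, sp) in enumerate(pairs):
                    surv, dis = apply_probe(ens, sp, instrument.field, probe, sub[i])
                    cell_survivors.append((surv, sp))
                    cell_dissociated.append((dis, sp))
                    # survivors share the parent arrays; reuse its cached TOF
                    tof_cache[id(surv)] = tof_cache[id(ens)]
                meta = {
                    "instrument": inst_meta,
                    "scenario": {
                        "voltage_V": voltage,
                        "probe": {
                            "delta_t_ns": delay / NS,
                            "slab_mm": [slab[0] / MM, slab[1] / MM],
                            "dissociation_prob": dissociation_prob,
                        },
                    },
                    "seed": grid.seed,
                }
                archive_probe[(voltage, tuple(slab), delay)] = render_spectrum(
                    cell_survivors,
                    cell_dissociated,
                    instrument,
                    bin_edges=bin_edges,
                    fragments_on=fragments_on,
                    shot_noise=shot_noise,
                    seed=sub[-1],
                    metadata=meta,
                    _tof_cache=tof_cache,
                )
    provenance = {
        "seed": grid.seed,
        "shots_per_spectrum": grid.shots_per_spectrum,
        "voltages_V": list(grid.voltages),
        "slabs_mm": [[s[0] / MM, s[1] / MM] for s in grid.slabs],
        "delays_ns": [d / NS for d in grid.delays],
        "species": [m.species.label for m in models],
        "models": [
            {
                "species": m.species.label,
                "tE_mean_ns": m.tE_mean / NS,
                "tE_sd_ns": m.tE_sd / NS,
                "v0_mean": m.v0_mean,
                "v0_sd": m.v0_sd,
                "ions_per_shot": m.ions_per_shot,
                "tE_shape": m.tE_shape,
            }
            for m in models
        ],
        "instrument": {
            "gap": instrument_template.gap,
            "drift_length": instrument_template.drift_length,
            "bin_width": instrument_template.bin_width,
        },
        "fragments_on": fragments_on,
        "shot_noise": shot_noise,
        "dissociation_prob": dissociation_prob,
    }
    return ScenarioArchive(
        baselines=archive_base,
        probed=archive_probe,
        instruments=instruments,
        provenance=provenance,
    )
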