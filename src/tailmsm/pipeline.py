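"""End-to-end pipeline: config, stage orchestration, fixtures, reporting.

The pipeline runs featurize -> score-features -> tICA -> cluster -> MSM ->
ITS -> PCCA+ -> CK -> kinetics -> report from a single validated config,
persisting every intermediate as CSV/HDF5/JSON so each stage consumes only
the persisted outputs of prior stages (restartable), and recording wall
times, warnings and content hashes of every output in a run record.
Identical config + inputs + seeds give identical output hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .coarse_grain import pcca
from .discretization import assign, fit_kmeans
from .featurization import (FeatureSetDefinition, FeatureTrajectory,
                            backbone_feature_set, featurize, rank_feature_sets)
from .kinetics import coarse_grained_kinetics, export_network
from .msm import MarkovStateModel, implied_timescales
from .synthetic import (EmissionModel, GroundTruthChain, PotentialSpec,
                        ToyTailSpec, emit_features, generate_langevin,
                        generate_markov_chain, generate_toy_tail)
from .tica import TICA, free_energy_surface

__version__ = "0.1.0"


class ConfigError(ValueError):
    """Raised for invalid configuration before any compute starts."""


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run.

    Lags are given in ns and must be whole multiples of the frame spacing
    ``dt_ns``.  Defaults follow the standard settings for this analysis:
    tICA/MSM lag 5 ns, k = 200 microstates, 4 macrostates.
    """

    inputs: list[str] = field(default_factory=list)
    input_format: str = "pdb"          # pdb | features_csv | features_h5
    system_name: str = "system"
    dt_ns: float = 1.0
    # features (used for coordinate inputs)
    feature_encoding: str = "sincos"
    torsions: object = "backbone"      # "backbone" or list of quadruplets
    distance_pairs: object = "auto"    # "auto" or list of pairs
    min_separation: int = 3
    # tICA
    tica_lag_ns: float = 5.0
    n_components: int | None = None
    var_cutoff: float = 0.95
    # clustering
    k: int = 200
    cluster_seed: int = 0
    cluster_stride: int = 1   # fit centers on every n-th frame; assign all
    # MSM
    msm_lag_ns: float = 5.0
    counting: str = "sliding"
    reversible: bool = True
    # validation
    its_lags_ns: list[float] = field(default_factory=lambda: [1.0, 2.0, 5.0, 10.0])
    its_m: int = 5
    ck_multiples: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    ck_n_boot: int = 50
    ck_seed: int = 0
    # coarse-graining / kinetics
    m_macrostates: int = 4
    source: int = 0
    sink: int | None = None
    max_paths: int = 10
    # output
    output_dir: str = "tailmsm_out"
    plots: bool = False

    def __post_init__(self):
        self.validate()

    def _frames(self, lag_ns: float, name: str) -> int:
        frames = lag_ns / self.dt_ns
        if abs(frames - round(frames)) > 1e-9 or round(frames) < 1:
            raise ConfigError(
                f"{name} = {lag_ns} ns is not a whole positive multiple of the "
                f"frame spacing {self.dt_ns} ns"
            )
        return int(round(frames))

    def validate(self) -> None:
        if self.input_format not in ("pdb", "features_csv", "features_h5"):
            raise ConfigError(f"unknown input_format {self.input_format!r}")
        if self.dt_ns <= 0:
            raise ConfigError("dt_ns must be positive")
        self._frames(self.tica_lag_ns, "tica_lag_ns")
        self._frames(self.msm_lag_ns, "msm_lag_ns")
        for lag in self.its_lags_ns:
            self._frames(lag, "its lag")
        if self.m_macrostates < 2:
            raise ConfigError("m_macrostates must be >= 2")
        if self.k < 2:
            raise ConfigError("k must be >= 2")
        for name in ("cluster_seed", "ck_seed"):
            if not isinstance(getattr(self, name), int):
                raise ConfigError(f"{name} must be an explicit integer")
        if self.counting not in ("sliding", "strided"):
            raise ConfigError("counting must be 'sliding' or 'strided'")

    @property
    def tica_lag_frames(self) -> int:
        return self._frames(self.tica_lag_ns, "tica_lag_ns")

    @property
    def msm_lag_frames(self) -> int:
        return self._frames(self.msm_lag_ns, "msm_lag_ns")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunRecord:
    """Provenance of one pipeline run: config, timings, warnings, hashes."""

    config: dict
    version: str = __version__
    stage_seconds: dict = field(default_factory=dict)
    warnings_: list[str] = field(default_factory=list)
    output_hashes: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# --------------------------------------------------------------------------
# stages (each reads persisted outputs of earlier stages)
# --------------------------------------------------------------------------

def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _feature_definition(config: PipelineConfig, n_atoms: int) -> FeatureSetDefinition:
    if config.torsions == "backbone" and config.distance_pairs == "auto":
        return backbone_feature_set(n_atoms, config.feature_encoding,
                                    config.min_separation)
    torsions = (tuple(tuple(q) for q in config.torsions)
                if config.torsions != "backbone"
                else backbone_feature_set(n_atoms).torsions)
    pairs = (tuple(tuple(p) for p in config.distance_pairs)
             if config.distance_pairs != "auto"
             else backbone_feature_set(n_atoms,
                                       min_separation=config.min_separation
                                       ).distance_pairs)
    return FeatureSetDefinition(torsions=torsions, distance_pairs=pairs,
                                encoding=config.feature_encoding)


def _load_coords(config: PipelineConfig) -> list[np.ndarray]:
    return [tio.read_pdb(p) for p in config.inputs]


def stage_featurize(config: PipelineConfig) -> Path:
    out = _outdir(config)
    if config.input_format == "pdb":
        coords = _load_coords(config)
        definition = _feature_definition(config, coords[0].shape[1])
        ftrajs = [featurize(c, definition, config.dt_ns, f"traj-{i:03d}")
                  for i, c in enumerate(coords)]
    elif config.input_format == "features_csv":
        ftrajs = [tio.read_features_csv(p, config.dt_ns, f"traj-{i:03d}")
                  for i, p in enumerate(config.inputs)]
    else:
        ftrajs = [f for p in config.inputs for f in tio.read_features_h5(p)]
    path = out / "features.h5"
    tio.write_features_h5(path, ftrajs)
    return path


def stage_score_features(config: PipelineConfig) -> Path:
    """VAMP-2 ranking of torsion-only / distance-only / combined feature sets.

    Only meaningful for coordinate (PDB) inputs; for precomputed features a
    single-candidate table is written.
    """
    out = _outdir(config)
    lags = sorted({max(1, config.tica_lag_frames // 2), config.tica_lag_frames,
                   2 * config.tica_lag_frames})
    if config.input_format == "pdb":
        coords = _load_coords(config)
        full = _feature_definition(config, coords[0].shape[1])
        candidates = {
            "torsions": FeatureSetDefinition(torsions=full.torsions,
                                             encoding=full.encoding),
            "distances": FeatureSetDefinition(distance_pairs=full.distance_pairs),
            "torsions+distances": full,
        }
        table = rank_feature_sets(coords, candidates, lags, dt_ns=config.dt_ns)
    else:
        from .featurization import vamp2_score
        ftrajs = tio.read_features_h5(out / "features.h5")
        rows = [{"feature_set": "input", "lag": lag,
                 "score_mean": vamp2_score(ftrajs, lag), "score_stderr": 0.0,
                 "n_splits": 1, "rank": 1} for lag in lags]
        table = pd.DataFrame(rows)
    path = out / "feature_ranking.csv"
    table.to_csv(path, index=False)
    return path


def stage_tica(config: PipelineConfig) -> Path:
    out = _outdir(config)
    ftrajs = tio.read_features_h5(out / "features.h5")
    model = TICA(ftrajs, config.tica_lag_frames, dt_ns=config.dt_ns)
    results = model.fit(n_components=config.n_components,
                        var_cutoff=config.var_cutoff)
    tio.write_tica_h5(out / "tica_model.h5", results)
    projections = results.transform(ftrajs)
    proj_trajs = [FeatureTrajectory(p, [f"IC{j + 1}" for j in range(p.shape[1])],
                                    config.dt_ns, f.traj_id)
                  for p, f in zip(projections, ftrajs)]
    tio.write_features_h5(out / "tica_projection.h5", proj_trajs)
    ic = np.vstack(projections)
    if ic.shape[1] >= 2:
        fes = free_energy_surface(ic[:, 0], ic[:, 1])
        tio.write_fes_csv(out / "free_energy_surface.csv", fes)
        if config.plots:
            from .plots import plot_fes
            plot_fes(fes, out / "free_energy_surface.png")
    (out / "tica_summary.txt").write_text(results.summary() + "\n")
    return out / "tica_model.h5"


def stage_cluster(config: PipelineConfig) -> Path:
    out = _outdir(config)
    proj = tio.read_features_h5(out / "tica_projection.h5")
    X = np.vstack([p.values for p in proj])
    model = fit_kmeans(X[::max(1, config.cluster_stride)], config.k,
                       seed=config.cluster_seed)
    pd.DataFrame(model.centers,
                 columns=[f"IC{j + 1}" for j in range(model.centers.shape[1])]
                 ).to_csv(out / "cluster_centers.csv", index=False)
    dtrajs = {p.traj_id: assign(model, p.values) for p in proj}
    tio.write_dtrajs_h5(out / "dtrajs.h5", dtrajs, config.dt_ns)
    for name, d in dtrajs.items():
        tio.write_dtraj_csv(out / f"dtraj_{name}.csv", d)
    return out / "dtrajs.h5"


def _fit_msm(config: PipelineConfig):
    out = _outdir(config)
    dtrajs = tio.read_dtrajs_h5(out / "dtrajs.h5")
    names = sorted(dtrajs)
    return MarkovStateModel([dtrajs[n] for n in names], config.msm_lag_frames,
                            dt_ns=config.dt_ns, counting=config.counting,
                            reversible=config.reversible).fit()


def stage_estimate(config: PipelineConfig) -> Path:
    out = _outdir(config)
    res = _fit_msm(config)
    pd.DataFrame(res.count_matrix.counts).to_csv(out / "counts.csv", index=False)
    pd.DataFrame(res.transition_matrix).to_csv(out / "transition_matrix.csv",
                                               index=False)
    pd.DataFrame({"microstate": res.active_set, "pi": res.stationary}
                 ).to_csv(out / "stationary.csv", index=False)
    pd.DataFrame({"eigenvalue": res.eigenvalues}).to_csv(
        out / "eigenvalues.csv", index=False)
    (out / "msm_summary.txt").write_text(res.summary() + "\n")
    return out / "transition_matrix.csv"


def stage_its(config: PipelineConfig) -> Path:
    out = _outdir(config)
    dtrajs = tio.read_dtrajs_h5(out / "dtrajs.h5")
    lags = [int(round(l / config.dt_ns)) for l in config.its_lags_ns]
    its = implied_timescales([dtrajs[n] for n in sorted(dtrajs)], lags,
                             m=config.its_m, dt_ns=config.dt_ns,
                             counting=config.counting,
                             reversible=config.reversible)
    its.to_dataframe().to_csv(out / "implied_timescales.csv", index=False)
    if config.plots:
        from .plots import plot_its
        plot_its(its, out / "implied_timescales.png")
    return out / "implied_timescales.csv"


def stage_pcca(config: PipelineConfig) -> Path:
    out = _outdir(config)
    res = _fit_msm(config)
    cg = pcca(res, config.m_macrostates)
    mem = pd.DataFrame(cg.memberships,
                       columns=[f"macro{j + 1}" for j in range(cg.m)])
    mem.insert(0, "microstate", cg.active_set)
    mem["crisp"] = cg.crisp
    mem.to_csv(out / "memberships.csv", index=False)
    pd.DataFrame({"macrostate": np.arange(cg.m) + 1,
                  "population_pct": 100.0 * cg.populations}
                 ).to_csv(out / "populations.csv", index=False)
    sets = {f"macro{j + 1}": s.tolist() for j, s in
            enumerate(cg.macrostate_sets())}
    (out / "macrostates.json").write_text(json.dumps(sets, indent=1) + "\n")
    return out / "macrostates.json"


def stage_ck(config: PipelineConfig) -> Path:
    out = _outdir(config)
    res = _fit_msm(config)
    sets = [np.asarray(v) for v in
            json.loads((out / "macrostates.json").read_text()).values()]
    ck = res.ck_test(sets, multiples=config.ck_multiples,
                     n_boot=config.ck_n_boot, seed=config.ck_seed)
    rows = []
    for k in ck.multiples:
        for a in range(len(sets)):
            for b in range(len(sets)):
                rows.append({
                    "multiple": k, "from_set": a + 1, "to_set": b + 1,
                    "estimated": ck.estimated[k][a, b],
                    "predicted": ck.predicted[k][a, b],
                    "stderr": ck.stderr[k][a, b],
                    "flagged": k in ck.flagged,
                })
    pd.DataFrame(rows).to_csv(out / "ck_test.csv", index=False)
    if config.plots:
        from .plots import plot_ck
        plot_ck(ck, out / "ck_test.png")
    return out / "ck_test.csv"


def stage_kinetics(config: PipelineConfig) -> Path:
    out = _outdir(config)
    res = _fit_msm(config)
    cg = pcca(res, config.m_macrostates)
    summary = coarse_grained_kinetics(res, cg, source=config.source,
                                      sink=config.sink,
                                      max_paths=config.max_paths)
    m = summary.m
    pd.DataFrame(summary.mfpt_ns,
                 columns=[f"to_macro{j + 1}" for j in range(m)]
                 ).to_csv(out / "mfpt.csv", index=False)
    pd.DataFrame(summary.rates_per_ns,
                 columns=[f"to_macro{j + 1}" for j in range(m)]
                 ).to_csv(out / "rates.csv", index=False)
    pd.DataFrame([{"path": " -> ".join(str(s + 1) for s in path),
                   "share_pct": share}
                  for path, share in summary.pathways]
                 ).to_csv(out / "pathways.csv", index=False)
    export_network(summary, dot_path=out / "network.dot",
                   json_path=out / "network.json")
    (out / "kinetics_summary.txt").write_text(summary.summary() + "\n")
    if config.plots:
        from .plots import plot_network
        plot_network(summary, out / "network.png")
    return out / "mfpt.csv"


def stage_report(config: PipelineConfig) -> Path:
    """One-row summary table per system: highest-population state and %,
    MFPT low/high (ns), total states, major transition path with share."""
    out = _outdir(config)
    pops = pd.read_csv(out / "populations.csv")
    mfpt = pd.read_csv(out / "mfpt.csv").to_numpy()
    missing = []
    try:
        paths = pd.read_csv(out / "pathways.csv")
        major = paths.iloc[0] if len(paths) else None
    except FileNotFoundError:
        missing.append("pathways")
        major = None
    m = len(pops)
    off = mfpt[~np.eye(m, dtype=bool)]
    off = off[off > 0]
    row = {
        "system": config.system_name,
        "highest_population_state": int(pops["population_pct"].idxmax()) + 1,
        "population_pct": round(float(pops["population_pct"].max()), 2),
        "mfpt_low_ns": round(float(off.min()), 4) if off.size else np.nan,
        "mfpt_high_ns": round(float(off.max()), 4) if off.size else np.nan,
        "total_states": m,
        "major_transition_path": "" if major is None else major["path"],
        "path_share_pct": np.nan if major is None else round(float(major["share_pct"]), 2),
        "missing_stages": ";".join(missing),
    }
    path = out / "report.csv"
    pd.DataFrame([row]).to_csv(path, index=False)
    return path


STAGES = [
    ("featurize", stage_featurize),
    ("score_features", stage_score_features),
    ("tica", stage_tica),
    ("cluster", stage_cluster),
    ("estimate", stage_estimate),
    ("its", stage_its),
    ("pcca", stage_pcca),
    ("ck", stage_ck),
    ("kinetics", stage_kinetics),
    ("report", stage_report),
]


def run_pipeline(config: PipelineConfig) -> RunRecord:
    """Run all stages in order; halt on the failing stage (partial outputs
    are retained).  Returns the run record, also written to run_record.json."""
    out = _outdir(config)
    config.to_yaml(out / "config.yaml")
    record = RunRecord(config=config.to_dict())
    for name, fn in STAGES:
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                fn(config)
            except Exception as exc:
                record.warnings_.append(f"stage {name} failed: {exc}")
                record.save(out / "run_record.json")
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        record.stage_seconds[name] = round(time.perf_counter() - t0, 4)
        record.warnings_.extend(f"{name}: {w.message}" for w in caught)
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "run_record.json":
            record.output_hashes[p.name] = _sha256(p)
    record.save(out / "run_record.json")
    return record


# --------------------------------------------------------------------------
# bundled synthetic fixtures
# --------------------------------------------------------------------------

def _two_state_truth() -> tuple[GroundTruthChain, EmissionModel]:
    T = np.array([[0.85, 0.15], [0.15, 0.85]])  # lambda_2 = 0.7
    chain = GroundTruthChain(T, lag_unit_ns=1.0)
    em = EmissionModel(means=np.array([[-1.0, 0.0], [1.0, 0.0]]),
                       covariances=np.array([0.05 * np.eye(2)] * 2))
    return chain, em


def _four_state_tail_truth() -> ToyTailSpec:
    # reversible by construction: symmetric transition counts
    S = np.array([
        [3400.0, 30.0, 12.0, 8.0],
        [30.0, 2730.0, 30.0, 10.0],
        [12.0, 30.0, 2130.0, 28.0],
        [8.0, 10.0, 28.0, 1454.0],
    ])
    T = S / S.sum(axis=1)[:, None]
    chain = GroundTruthChain(T, lag_unit_ns=1.0)
    return ToyTailSpec(
        n_residues=8,
        torsion_means=np.array([-2.5, -0.9, 0.7, 2.3]),
        torsion_concentrations=np.array([25.0, 25.0, 25.0, 25.0]),
        chain=chain, bond_length=3.8,
    )


def _double_well_spec(n_steps: int, seed: int) -> PotentialSpec:
    # depths chosen so a 10^6-step walk crosses between wells several
    # hundred times: the basin free-energy difference is then resolvable
    # to a few hundredths of a kcal/mol while the basins stay distinct
    return PotentialSpec(
        dimension=2,
        centers=np.array([[-1.0, 0.0], [1.0, 0.0]]),
        depths=np.array([3.0, 2.0]),
        widths=np.array([0.55, 0.55]),
        kT=1.0, friction=1.0, dt=0.005, n_steps=n_steps, seed=seed,
    )


FIXTURES = ("two_state", "four_state_tail", "double_well")


def simulate_fixture(name: str, seed: int, outdir=None,
                     n_trajs: int | None = None,
                     n_frames: int | None = None) -> dict:
    """Generate a named synthetic dataset with its ground-truth parameters.

    ``two_state``       : 2-state chain (lambda_2 = 0.7) with 2D Gaussian
                          emissions; features written to HDF5.
    ``four_state_tail`` : 8-bead toy tail driven by a reversible 4-state
                          chain; coordinates written as multi-model PDB
                          (first trajectory only, for format round-trips)
                          plus hidden-state CSVs.
    ``double_well``     : 2D overdamped Langevin walk in an asymmetric
                          double well; coordinates written as CSV.

    Returns a dict with the in-memory data and truth objects; when
    ``outdir`` is given the dataset and a ``truth.json`` are written there.
    Same name + seed always produces identical files.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    out = None
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
    if name == "two_state":
        n_trajs = 4 if n_trajs is None else n_trajs
        n_frames = 50_000 if n_frames is None else n_frames
        chain, em = _two_state_truth()
        states, ftrajs = [], []
        for i in range(n_trajs):
            s = generate_markov_chain(chain, n_frames, seed=seed + 17 * i)
            X = emit_features(s, em, seed=seed + 17 * i + 1)
            states.append(s)
            ftrajs.append(FeatureTrajectory(X, ["x", "y"], 1.0, f"traj-{i:03d}"))
        truth = {"transition_matrix": chain.transition_matrix.tolist(),
                 "stationary": chain.stationary.tolist(),
                 "eigenvalues": np.real(chain.eigenvalues()).tolist(),
                 "lag_unit_ns": chain.lag_unit_ns, "seed": seed}
        if out:
            tio.write_features_h5(out / "features.h5", ftrajs)
            for i, s in enumerate(states):
                tio.write_dtraj_csv(out / f"hidden_states_{i:03d}.csv", s)
            (out / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")
        return {"chain": chain, "emissions": em, "states": states,
                "features": ftrajs, "truth": truth}
    if name == "four_state_tail":
        n_trajs = 8 if n_trajs is None else n_trajs
        n_frames = 25_000 if n_frames is None else n_frames
        spec = _four_state_tail_truth()
        coords, states = [], []
        for i in range(n_trajs):
            c, s = generate_toy_tail(spec, n_frames, seed=seed + 101 * i)
            coords.append(c)
            states.append(s)
        truth = {"transition_matrix": spec.chain.transition_matrix.tolist(),
                 "stationary": spec.chain.stationary.tolist(),
                 "torsion_means": spec.torsion_means.tolist(),
                 "n_residues": spec.n_residues,
                 "bond_length": spec.bond_length, "seed": seed}
        if out:
            tio.write_pdb(out / "tail_000.pdb", coords[0][:200])
            for i, s in enumerate(states):
                tio.write_dtraj_csv(out / f"hidden_states_{i:03d}.csv", s)
            (out / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")
        return {"spec": spec, "chain": spec.chain, "coords": coords,
                "states": states, "truth": truth}
    # double_well
    n_frames = 200_000 if n_frames is None else n_frames
    spec = _double_well_spec(n_frames, seed)
    xy = generate_langevin(spec)
    truth = {"centers": spec.centers.tolist(), "depths": spec.depths.tolist(),
             "widths": spec.widths.tolist(), "kT": spec.kT,
             "friction": spec.friction, "dt": spec.dt, "seed": seed}
    if out:
        pd.DataFrame(xy, columns=["x", "y"]).to_csv(out / "double_well.csv",
                                                    index=False)
        (out / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")
    return {"spec": spec, "coords": xy, "truth": truth}
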