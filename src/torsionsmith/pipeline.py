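"""End-to-end orchestration: conformers -> centroids -> torsion selection ->
fragmentation -> reference scans -> fitting -> merged outputs.

Every step persists its artifacts into a numbered subdirectory of the run
directory (plain text: JSON, prmtop, two-column profiles), so a run can be
inspected, edited, and resumed from any step.  With fixed seeds a full run is
deterministic down to the bytes of the final frcmod.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import conformers as conf_mod
from . import io_formats as iof
from .ffcore import Conformation, FourierComponent, MoleculeTopology, TorsionTerm
from .fragmentor import (FragmentSpec, decide_fragmentation,
                         fragment_coordinates, plan_fragments)
from .scan_engine import (InternalMMBackend, ScanProfile, make_grid, run_scan,
                          select_best_profile)
from .synthetic import mock_qm_backend
from .torsion_fit import FitSpec, boltzmann_average_charges, fit_torsion
from .torsion_select import (TorsionKey, backbone_connected,
                             enumerate_candidates, longest_heavy_chain, prune,
                             wrapped_dispersion)

log = logging.getLogger(__name__)

STEPS = ("conformers", "centroids", "selection", "fragmentation", "scans",
         "fit", "outputs")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "resume", "STEPS"]


@dataclass
class RunConfig:
    seed: int = 0
    n_conformers: int = 300
    conformer_backend: str = "fixture"
    energy_window: float = 3.5          # kcal/mol centroid retention window
    dispersion_cutoff: float = 30.0     # degrees
    grid_spacing: float = 20.0          # degrees (18 points over 360)
    temperature: float = 298.0          # K, Boltzmann weights
    restraint_k: float = 500.0          # kcal/mol/rad^2
    restraint_tol: float = 0.5          # degrees
    min_convergence: float = 1e-4       # kcal/mol/A max-gradient
    fit_mode: str = "full"
    fit_basis: tuple[int, ...] = (1, 2, 3, 4)
    fit_convergence: float = 0.001      # kcal/mol outer profile-RMSD change
    max_outer: int = 10
    prune_floor: float = 0.005
    exclude_terminal: bool = True
    exclude_ring: bool = True
    cut_fraction: float = 0.25
    max_clusters: int = 10
    size_threshold: int = 35
    reference_backend: str = "mock-qm"  # or "internal-mm"
    perturbation_seed: int = 0

    def __post_init__(self):
        if self.energy_window <= 0 or self.temperature <= 0:
            raise ValueError("energy_window and temperature must be positive")
        if 360.0 % self.grid_spacing:
            raise ValueError("grid_spacing must divide 360")
        self.fit_basis = tuple(self.fit_basis)

    def fit_spec(self) -> FitSpec:
        return FitSpec(mode=self.fit_mode, basis=self.fit_basis,
                       convergence=self.fit_convergence,
                       max_outer=self.max_outer, prune_floor=self.prune_floor,
                       retry_seed=self.seed)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunReport:
    steps: dict = field(default_factory=dict)   # name -> {status, seconds, artifacts}
    significant: list = field(default_factory=list)
    fits: list = field(default_factory=list)
    manifest: list = field(default_factory=list)
    stopped_after: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=float)


def _reference_backend_for(cfg: RunConfig, topology: MoleculeTopology):
    mm = InternalMMBackend(cfg.restraint_k, cfg.restraint_tol,
                           cfg.min_convergence)
    if cfg.reference_backend == "internal-mm":
        return mm
    if cfg.reference_backend == "mock-qm":
        return mock_qm_backend(topology, cfg.perturbation_seed)
    raise ValueError(f"unknown reference backend {cfg.reference_backend!r}")


# --- artifact (de)serialization helpers ------------------------------------

def _save_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=1, default=float))


def _load_json(path):
    return json.loads(Path(path).read_text())


def _confs_to_obj(confs):
    return [c.coordinates.tolist() for c in confs]


def _confs_from_obj(obj):
    return [Conformation(np.array(x)) for x in obj]


def _key_to_obj(t: TorsionKey, extra=None):
    d = {"quad": list(t.quad), "central": list(t.central),
         "type_quad": list(t.type_quad), "backbone_depth": t.backbone_depth}
    if extra:
        d.update(extra)
    return d


def _key_from_obj(d) -> TorsionKey:
    return TorsionKey(tuple(d["quad"]), tuple(d["central"]),
                      tuple(d["type_quad"]), d["backbone_depth"])


def _term_to_obj(term: TorsionTerm):
    return {"quad": list(term.quad),
            "components": [[c.v, c.n, c.gamma] for c in term.components],
            "scee": term.scee, "scnb": term.scnb}


def _term_from_obj(d) -> TorsionTerm:
    return TorsionTerm(tuple(d["quad"]),
                       tuple(FourierComponent(v, int(n), g)
                             for v, n, g in d["components"]),
                       d["scee"], d["scnb"])


class _Run:
    """Working state + persistence for one pipeline run."""

    def __init__(self, out_dir, cfg: RunConfig, topology=None,
                 conformations=None, charge_sets=None):
        self.dir = Path(out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.cfg = cfg
        self.topology = topology
        self.conformations = conformations
        self.charge_sets = charge_sets
        self.report = RunReport()
        # state produced by steps
        self.ensemble = None
        self.centroids = None
        self.avg_charges = None
        self.significant: list[TorsionKey] = []
        self.chain: list[int] = []
        self.backbone: list[TorsionKey] = []
        self.fragments: list[FragmentSpec] = []
        self.assignment: dict = {}     # canonical parent quad -> fragment idx or None
        self.profiles: dict = {}       # canonical parent quad -> ScanProfile (local quad)
        self.fit_results: dict = {}

    def step_dir(self, name) -> Path:
        d = self.dir / f"step{STEPS.index(name) + 1:02d}_{name}"
        d.mkdir(exist_ok=True)
        return d

    def save_inputs(self):
        d = self.dir / "step00_inputs"
        d.mkdir(exist_ok=True)
        iof.write_topology(d / "parent.prmtop", self.topology)
        _save_json(d / "conformations.json", _confs_to_obj(self.conformations))
        if self.charge_sets is not None:
            _save_json(d / "charge_sets.json",
                       [np.asarray(q).tolist() for q in self.charge_sets])
        self.cfg.to_yaml(self.dir / "config.yaml")

    def load_inputs(self):
        d = self.dir / "step00_inputs"
        if not d.exists():
            raise FileNotFoundError(f"missing inputs for run at {self.dir}")
        self.topology = iof.read_topology(d / "parent.prmtop")
        self.conformations = _confs_from_obj(_load_json(d / "conformations.json"))
        qpath = d / "charge_sets.json"
        self.charge_sets = ([np.array(q) for q in _load_json(qpath)]
                            if qpath.exists() else None)


# --- steps ------------------------------------------------------------------

def _step_conformers(run: _Run):
    cfg = run.cfg
    ens = conf_mod.generate_conformers(run.conformations, cfg.n_conformers,
                                       cfg.seed, backend=cfg.conformer_backend)
    ens = conf_mod.minimize_ensemble(ens, "internal-mm", run.topology,
                                     cfg.min_convergence)
    run.ensemble = ens
    d = run.step_dir("conformers")
    _save_json(d / "ensemble.json",
               {"coordinates": _confs_to_obj(ens.conformations),
                "energies": ens.energies.tolist(),
                "kept_indices": getattr(ens, "kept_indices",
                                        list(range(len(ens.conformations)))),
                "backend": ens.backend, "seed": cfg.seed})


def _load_conformers(run: _Run):
    obj = _load_json(run.step_dir("conformers") / "ensemble.json")
    ens = conf_mod.ConformerEnsemble(_confs_from_obj(obj["coordinates"]),
                                     np.array(obj["energies"]),
                                     obj["backend"], obj["seed"])
    ens.kept_indices = obj["kept_indices"]
    run.ensemble = ens


def _step_centroids(run: _Run):
    cfg = run.cfg
    cs = conf_mod.cluster_centroids(run.ensemble, run.topology,
                                    cfg.cut_fraction, cfg.max_clusters,
                                    cfg.temperature)
    cs = conf_mod.filter_by_energy_window(cs, cfg.energy_window)
    run.centroids = cs
    if run.charge_sets is not None:
        kept = getattr(run.ensemble, "kept_indices",
                       list(range(len(run.ensemble.conformations))))
        per_centroid = [np.asarray(run.charge_sets[kept[m]])
                        for m in cs.member_indices]
        run.avg_charges = boltzmann_average_charges(per_centroid, cs)
    d = run.step_dir("centroids")
    _save_json(d / "centroids.json",
               {"coordinates": _confs_to_obj(cs.conformations),
                "relative_energies": cs.relative_energies.tolist(),
                "weights": cs.weights.tolist(),
                "member_indices": cs.member_indices,
                "temperature": cs.temperature,
                "avg_charges": (run.avg_charges.tolist()
                                if run.avg_charges is not None else None)})


def _load_centroids(run: _Run):
    obj = _load_json(run.step_dir("centroids") / "centroids.json")
    run.centroids = conf_mod.CentroidSet(
        _confs_from_obj(obj["coordinates"]), np.array(obj["relative_energies"]),
        np.array(obj["weights"]), obj["member_indices"], obj["temperature"])
    run.avg_charges = (np.array(obj["avg_charges"])
                       if obj.get("avg_charges") is not None else None)


def _step_selection(run: _Run):
    cfg = run.cfg
    cands = enumerate_candidates(run.topology)
    disp = {c.canonical: wrapped_dispersion(run.centroids.conformations, c)
            for c in cands}
    run.significant = prune(run.topology, cands, disp, cfg.dispersion_cutoff,
                            cfg.exclude_terminal, cfg.exclude_ring)
    run.chain = longest_heavy_chain(run.topology)
    run.backbone = backbone_connected(run.significant, run.chain)
    bb = {t.canonical for t in run.backbone}
    run.report.significant = [
        _key_to_obj(t, {"dispersion": disp[t.canonical],
                        "backbone_connected": t.canonical in bb})
        for t in run.significant]
    d = run.step_dir("selection")
    _save_json(d / "selection.json",
               {"significant": run.report.significant, "chain": run.chain,
                "n_candidates": len(cands)})


def _load_selection(run: _Run):
    obj = _load_json(run.step_dir("selection") / "selection.json")
    run.significant = [_key_from_obj(d) for d in obj["significant"]]
    run.chain = obj["chain"]
    run.backbone = backbone_connected(run.significant, run.chain)
    run.report.significant = obj["significant"]


def _step_fragmentation(run: _Run):
    cfg = run.cfg
    base_conf = run.centroids.conformations[0]
    run.fragments = plan_fragments(run.topology, base_conf, run.significant,
                                   cfg.size_threshold)
    run.assignment = {}
    for t in run.significant:
        frag_idx = None
        for fi, fr in enumerate(run.fragments):
            if any(t.canonical == m.canonical for m in fr.region.torsions):
                frag_idx = fi
                break
        run.assignment[t.canonical] = frag_idx
    d = run.step_dir("fragmentation")
    decision = decide_fragmentation(run.topology, run.significant,
                                    cfg.size_threshold)
    meta = {"fragment": decision.fragment, "rationale": decision.rationale,
            "n_regions": decision.n_regions,
            "assignment": {str(list(k)): v for k, v in run.assignment.items()},
            "fragments": []}
    for fi, fr in enumerate(run.fragments):
        iof.write_topology(d / f"frag{fi}.prmtop", fr.topology)
        iof.write_atom_map(d / f"frag{fi}_map.json", fr.atom_map)
        iof.write_mol2(d / f"frag{fi}.mol2", fr.topology, fr.conformation)
        meta["fragments"].append({
            "cleaved_bonds": [list(b) for b in fr.cleaved_bonds],
            "cap_info": [[c, i, o, list(h)] for c, i, o, h in fr.cap_info],
            "region_quads": [list(t.quad) for t in fr.region.torsions]})
    _save_json(d / "fragmentation.json", meta)


def _load_fragmentation(run: _Run):
    from .fragmentor import TorsionRegion
    d = run.step_dir("fragmentation")
    meta = _load_json(d / "fragmentation.json")
    run.fragments = []
    sig_by_canon = {t.canonical: t for t in run.significant}
    for fi, fmeta in enumerate(meta["fragments"]):
        top = iof.read_topology(d / f"frag{fi}.prmtop")
        amap = iof.read_atom_map(d / f"frag{fi}_map.json")
        members = [sig_by_canon[min(tuple(q), tuple(q)[::-1])]
                   for q in fmeta["region_quads"]]
        atoms = set()
        for t in members:
            atoms.update(t.quad)
        region = TorsionRegion(members, atoms, {t.central for t in members})
        _, xyz, _, _ = iof.read_mol2(d / f"frag{fi}.mol2")
        run.fragments.append(FragmentSpec(
            top, Conformation(xyz), amap,
            [tuple(b) for b in fmeta["cleaved_bonds"]], region,
            [(c, i, o, list(h)) for c, i, o, h in fmeta["cap_info"]]))
    run.assignment = {tuple(json.loads(k)): v
                      for k, v in meta["assignment"].items()}


def _scan_context(run: _Run, key: TorsionKey):
    """(topology, local quad, conformation-for-centroid fn) for a torsion,
    resolved through its fragment when one exists."""
    frag_idx = run.assignment.get(key.canonical)
    if frag_idx is None:
        return (run.topology, key.quad,
                lambda ci: run.centroids.conformations[ci])
    fr = run.fragments[frag_idx]
    return (fr.topology, fr.map_quad(key.quad),
            lambda ci: fragment_coordinates(fr, run.centroids.conformations[ci]))


def _step_scans(run: _Run):
    cfg = run.cfg
    grid = make_grid(cfg.grid_spacing)
    d = run.step_dir("scans")
    run.profiles = {}
    meta = {}
    for ti, key in enumerate(run.significant):
        top, quad, conf_for = _scan_context(run, key)
        backend = _reference_backend_for(cfg, top)
        candidates = []
        for ci in range(len(run.centroids)):
            prof = run_scan(backend, top, conf_for(ci), quad, grid,
                            origin_centroid=ci)
            candidates.append(prof)
            iof_path = d / f"torsion{ti}_centroid{ci}.dat"
            from .scan_engine import write_profile
            write_profile(iof_path, prof)
        best = select_best_profile(candidates)
        run.profiles[key.canonical] = best
        meta[str(ti)] = {"quad": list(key.quad), "local_quad": list(best.key),
                         "origin_centroid": best.origin_centroid,
                         "degraded": best.degraded, "backend": best.backend,
                         "angles": list(best.grid.angles),
                         "energies": best.energies.tolist()}
    _save_json(d / "scans.json", meta)


def _load_scans(run: _Run):
    cfg = run.cfg
    meta = _load_json(run.step_dir("scans") / "scans.json")
    grid = make_grid(cfg.grid_spacing)
    run.profiles = {}
    for ti, key in enumerate(run.significant):
        m = meta[str(ti)]
        prof = ScanProfile(tuple(m["local_quad"]), grid,
                           np.array(m["energies"]),
                           [None] * len(m["energies"]), m["backend"],
                           m["origin_centroid"], m["degraded"])
        run.profiles[key.canonical] = prof


def _step_fit(run: _Run):
    cfg = run.cfg
    grid = make_grid(cfg.grid_spacing)
    mm = InternalMMBackend(cfg.restraint_k, cfg.restraint_tol,
                           cfg.min_convergence)
    spec = cfg.fit_spec()
    run.fit_results = {}
    d = run.step_dir("fit")
    out = {}
    for ti, key in enumerate(run.significant):
        top, quad, conf_for = _scan_context(run, key)
        ref = run.profiles[key.canonical]
        start = conf_for(ref.origin_centroid)

        def mm_scan(t, _start=start, _quad=quad):
            return run_scan(mm, t, _start, _quad, grid)

        res = fit_torsion(top, quad, ref, spec, mm_scan=mm_scan)
        run.fit_results[key.canonical] = res
        out[str(ti)] = {"parent_quad": list(key.quad),
                        "term": _term_to_obj(res.term),
                        "initial_rmse": res.initial_rmse,
                        "final_rmse": res.final_rmse,
                        "outer_cycles": res.outer_cycles,
                        "converged": res.converged, "trace": res.trace}
    _save_json(d / "fit_results.json", out)
    run.report.fits = list(out.values())


def _load_fit(run: _Run):
    from .torsion_fit import FitResult
    out = _load_json(run.step_dir("fit") / "fit_results.json")
    run.fit_results = {}
    for ti, key in enumerate(run.significant):
        m = out[str(ti)]
        run.fit_results[key.canonical] = FitResult(
            tuple(m["term"]["quad"]), _term_from_obj(m["term"]),
            m["initial_rmse"], m["final_rmse"], m["outer_cycles"], 0,
            m["converged"], m["trace"])
    run.report.fits = list(out.values())


def _step_outputs(run: _Run):
    d = run.step_dir("outputs")
    entries = []
    doc = iof.FrcmodDocument()
    for key in run.significant:
        res = run.fit_results[key.canonical]
        frag_idx = run.assignment.get(key.canonical)
        if frag_idx is None:
            top, amap = run.topology, None
        else:
            fr = run.fragments[frag_idx]
            top, amap = fr.topology, fr.atom_map
        entries.append(iof.FitEntry(res.key, res.term, top, amap))
        tq = iof.type_quadruple(top, res.key)
        if tq in doc.dihe and doc.dihe[tq].components != res.term.components:
            log.warning("frcmod merge conflict on %s; last fit wins", tq)
        doc.dihe[tq] = replace(res.term, quad=res.key)
    (d / "final.frcmod").write_text(doc.to_text())
    script = iof.write_parmed_script(entries, run.topology)
    (d / "parmed.in").write_text(script.to_text())
    conf0 = run.centroids.conformations[0]
    iof.write_mol2(d / "final.mol2", run.topology, conf0, run.avg_charges)
    for fi, fr in enumerate(run.fragments):
        iof.write_atom_map(d / f"frag{fi}_map.json", fr.atom_map)
    run.report.manifest = sorted(str(p.relative_to(run.dir))
                                 for p in run.dir.rglob("*") if p.is_file())


_STEP_FUNCS = {"conformers": (_step_conformers, _load_conformers),
               "centroids": (_step_centroids, _load_centroids),
               "selection": (_step_selection, _load_selection),
               "fragmentation": (_step_fragmentation, _load_fragmentation),
               "scans": (_step_scans, _load_scans),
               "fit": (_step_fit, _load_fit),
               "outputs": (_step_outputs, None)}


def _execute(run: _Run, start_index: int) -> RunReport:
    for si, name in enumerate(STEPS):
        compute, load = _STEP_FUNCS[name]
        t0 = time.perf_counter()
        try:
            if si < start_index:
                if load is not None:
                    load(run)
                run.report.steps[name] = {"status": "loaded", "seconds": 0.0}
                continue
            compute(run)
        except FileNotFoundError as err:
            raise FileNotFoundError(
                f"cannot resume: missing artifact for step {name!r}: {err}"
            ) from err
        except Exception as err:
            run.report.steps[name] = {"status": f"failed: {err}",
                                      "seconds": time.perf_counter() - t0}
            run.report.stopped_after = name
            log.exception("step %s failed", name)
            break
        run.report.steps[name] = {"status": "ok",
                                  "seconds": round(time.perf_counter() - t0, 3)}
        if name == "selection" and not run.significant:
            run.report.stopped_after = name
            log.info("no significant torsions; stopping after selection")
            break
    _save_json(run.dir / "manifest.json", asdict(run.report))
    (run.dir / "summary.txt").write_text(_summary_text(run))
    return run.report


def _summary_text(run: _Run) -> str:
    lines = [f"torsionsmith run in {run.dir}", ""]
    for name, st in run.report.steps.items():
        lines.append(f"  {name:<14s} {st['status']} ({st['seconds']:.2f} s)")
    lines.append("")
    lines.append(f"significant torsions: {len(run.significant)}")
    for t, fit in zip(run.significant, run.report.fits):
        lines.append(f"  {t.quad}  RMSE {fit['initial_rmse']:.4f} -> "
                     f"{fit['final_rmse']:.4f} kcal/mol")
    return "\n".join(lines) + "\n"


def run_pipeline(topology: MoleculeTopology, conformations, config: RunConfig,
                 out_dir, charge_sets=None) -> RunReport:
    """Execute the full workflow and persist every step under ``out_dir``."""
    run = _Run(out_dir, config, topology, list(conformations), charge_sets)
    run.save_inputs()
    return _execute(run, 0)


def resume(run_dir, from_step: str) -> RunReport:
    """Recompute from ``from_step`` onward, loading earlier artifacts from the
    run directory; identical outputs to a fresh run when nothing changed."""
    if from_step not in STEPS:
        raise ValueError(f"unknown step {from_step!r}; choose from {STEPS}")
    cfg = RunConfig.from_yaml(Path(run_dir) / "config.yaml")
    run = _Run(run_dir, cfg)
    run.load_inputs()
    return _execute(run, STEPS.index(from_step))
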