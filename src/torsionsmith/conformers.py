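"""Conformer ensemble generation, minimization, clustering, and centroid
selection.

Each minimized conformer is represented by a two-feature vector: heavy-atom
RMSD (after Kabsch superposition) to the lowest-energy conformer, and its
relative energy.  Both feature columns are L2-normalized across the ensemble
so they combine into one Euclidean distance without a unit conversion, and
Ward hierarchical clustering groups them.  Each cluster is represented by its
lowest-energy member (the centroid); centroids above an energy window
(default 3.5 kcal/mol) are discarded and the rest receive Boltzmann weights
at 298 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .ffcore import Conformation, MoleculeTopology, restrained_minimize

KBOLTZ = 0.0019872041   # kcal/mol/K

__all__ = [
    "KBOLTZ", "ConformerEnsemble", "CentroidSet", "generate_conformers",
    "minimize_ensemble", "cluster_centroids", "filter_by_energy_window",
    "boltzmann_weights", "kabsch_rmsd",
]


@dataclass
class ConformerEnsemble:
    conformations: list[Conformation]
    energies: np.ndarray | None = None     # kcal/mol
    backend: str = "unspecified"
    seed: int | None = None

    def __post_init__(self):
        ns = {c.coordinates.shape[0] for c in self.conformations}
        if len(ns) > 1:
            raise ValueError("inconsistent atom counts across conformers")
        if self.energies is not None:
            self.energies = np.asarray(self.energies, float)
            if not np.all(np.isfinite(self.energies)):
                raise ValueError("non-finite conformer energies")


@dataclass
class CentroidSet:
    conformations: list[Conformation]
    relative_energies: np.ndarray          # dE_k = E_k - E_min, kcal/mol
    weights: np.ndarray = field(default=None)  # Boltzmann, sums to 1
    member_indices: list[int] = field(default_factory=list)  # into the ensemble
    temperature: float = 298.0

    def __post_init__(self):
        self.relative_energies = np.asarray(self.relative_energies, float)
        if len(self.relative_energies) and abs(self.relative_energies.min()) > 1e-12:
            raise ValueError("relative energies must have minimum 0")
        if self.weights is None:
            self.weights = boltzmann_weights(self.relative_energies,
                                             self.temperature)

    def __len__(self):
        return len(self.conformations)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between coordinate sets after optimal rigid-body superposition."""
    pa = a - a.mean(axis=0)
    pb = b - b.mean(axis=0)
    h = pa.T @ pb
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return float(np.sqrt(np.mean(np.sum((pa @ rot.T - pb) ** 2, axis=1))))


def generate_conformers(molecule, n_conformers: int = 300, seed: int = 0,
                        backend: str | Callable = "etkdg") -> ConformerEnsemble:
    """Embed 3D conformers.

    ``molecule`` is an RDKit Mol (explicit hydrogens) for the
    distance-geometry default backend, or anything the provided callable /
    fixture backend understands.  ``backend``:

    * ``"etkdg"`` — RDKit ETKDG distance-geometry embedding (seeded);
    * ``"fixture"`` — ``molecule`` is a sequence of prebuilt
      :class:`Conformation` objects, returned as-is;
    * a callable ``(molecule, n_conformers, seed) -> list[Conformation]``.
    """
    if backend == "fixture":
        confs = list(molecule)
        if not confs:
            raise RuntimeError("fixture backend produced zero conformers")
        return ConformerEnsemble(confs, backend="fixture", seed=seed)
    if callable(backend):
        confs = list(backend(molecule, n_conformers, seed))
        if not confs:
            raise RuntimeError("conformer backend produced zero conformers")
        return ConformerEnsemble(confs, backend=getattr(backend, "__name__",
                                                        "callable"), seed=seed)
    from rdkit.Chem import AllChem  # deferred: only the ETKDG path needs it
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    ids = AllChem.EmbedMultipleConfs(molecule, numConfs=int(n_conformers),
                                     params=params)
    if len(ids) == 0:
        raise RuntimeError("ETKDG embedding produced zero conformers")
    confs = [Conformation(np.array(molecule.GetConformer(i).GetPositions()))
             for i in ids]
    return ConformerEnsemble(confs, backend="etkdg", seed=seed)


def minimize_ensemble(ensemble: ConformerEnsemble,
                      backend: "str | object" = "internal-mm",
                      topology: MoleculeTopology | None = None,
                      convergence: float = 1e-4) -> ConformerEnsemble:
    """Minimize every conformer; ordering preserved, failures dropped with a
    warning (all-failed is an error).

    ``backend``: "internal-mm" (needs ``topology``) or an object with a
    ``minimize(conformation) -> (Conformation, energy)`` method (fixture
    oracles, external adapters).
    """
    import warnings
    out_confs, out_e, kept = [], [], []
    for idx, conf in enumerate(ensemble.conformations):
        try:
            if backend == "internal-mm":
                if topology is None:
                    raise ValueError("internal-mm backend requires a topology")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    res = restrained_minimize(topology, conf,
                                              convergence=convergence)
                mconf, e = res.conformation, res.energy
            else:
                mconf, e = backend.minimize(conf)
        except Exception as err:  # pragma: no cover - backend-specific
            warnings.warn(f"conformer {idx} dropped: {err}", RuntimeWarning,
                          stacklevel=2)
            continue
        out_confs.append(mconf)
        out_e.append(float(e))
        kept.append(idx)
    if not out_confs:
        raise RuntimeError("every conformer failed to minimize")
    tag = backend if isinstance(backend, str) else getattr(backend, "name",
                                                           "custom")
    ens = ConformerEnsemble(out_confs, np.array(out_e), tag, ensemble.seed)
    ens.kept_indices = kept
    return ens


def _feature_matrix(ensemble: ConformerEnsemble,
                    heavy: Sequence[int]) -> np.ndarray:
    e = ensemble.energies
    ref = int(np.argmin(e))
    ref_xyz = ensemble.conformations[ref].coordinates[list(heavy)]
    rmsd = np.array([kabsch_rmsd(c.coordinates[list(heavy)], ref_xyz)
                     for c in ensemble.conformations])
    de = e - e[ref]
    feats = np.column_stack([rmsd, de])
    for col in range(feats.shape[1]):
        norm = np.linalg.norm(feats[:, col])
        if norm > 0:   # an all-zero column is left as zeros
            feats[:, col] = feats[:, col] / norm
    return feats


def cluster_centroids(ensemble: ConformerEnsemble,
                      topology: MoleculeTopology | None = None,
                      cut_fraction: float = 0.25,
                      max_clusters: int = 10,
                      temperature: float = 298.0) -> CentroidSet:
    """Ward-cluster the (heavy-atom RMSD, relative energy) features and take
    each cluster's lowest-energy member as its centroid.

    The dendrogram is cut at ``cut_fraction`` of the maximum merge height
    (minimum one cluster); if that yields more than ``max_clusters`` clusters
    the cut is tightened to exactly ``max_clusters``.
    """
    if ensemble.energies is None:
        raise ValueError("ensemble must be minimized (energies required)")
    k = len(ensemble.conformations)
    heavy = (topology.heavy_atoms() if topology is not None
             else list(range(ensemble.conformations[0].coordinates.shape[0])))
    if k == 1:
        return CentroidSet(list(ensemble.conformations), np.zeros(1),
                           member_indices=[0], temperature=temperature)
    feats = _feature_matrix(ensemble, heavy)
    z = linkage(feats, method="ward")
    hmax = float(z[:, 2].max())
    if hmax <= 0.0:
        labels = np.ones(k, dtype=int)
    else:
        labels = fcluster(z, t=cut_fraction * hmax, criterion="distance")
        if labels.max() > min(max_clusters, k):
            labels = fcluster(z, t=min(max_clusters, k), criterion="maxclust")
    centroids = []
    for lab in range(1, labels.max() + 1):
        members = np.where(labels == lab)[0]
        centroids.append(members[np.argmin(ensemble.energies[members])])
    centroids.sort(key=lambda m: ensemble.energies[m])
    e = ensemble.energies[centroids]
    return CentroidSet([ensemble.conformations[m] for m in centroids],
                       e - e.min(), member_indices=[int(m) for m in centroids],
                       temperature=temperature)


def filter_by_energy_window(centroids: CentroidSet,
                            energy_window: float = 3.5) -> CentroidSet:
    """Retain centroids with dE_k <= window (boundary inclusive); the global
    minimum always survives; weights are renormalized.  Idempotent."""
    if energy_window <= 0:
        raise ValueError("energy window must be positive")
    keep = [i for i, de in enumerate(centroids.relative_energies)
            if de <= energy_window]
    return CentroidSet([centroids.conformations[i] for i in keep],
                       centroids.relative_energies[keep],
                       member_indices=[centroids.member_indices[i]
                                       for i in keep] if centroids.member_indices
                       else [],
                       temperature=centroids.temperature)


def boltzmann_weights(relative_energies, temperature: float = 298.0) -> np.ndarray:
    """w_k proportional to exp(-dE_k / kB T), normalized to sum 1."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    de = np.asarray(relative_energies, float)
    if de.size == 0:
        return np.zeros(0)
    w = np.exp(-(de - de.min()) / (KBOLTZ * temperature))
    return w / w.sum()
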