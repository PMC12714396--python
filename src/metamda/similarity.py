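"""Microbe and drug similarity measures.

Two families feed the similarity-gated ``ss``/``dd`` edges of the
heterogeneous graph:

* **Gaussian interaction profile (GIP) kernel** similarity between the
  binary interaction profiles of two nodes,
  ``GM(i, j) = exp(-eta * ||I_i - I_j||^2)``, with kernel bandwidth
  ``eta = eta' / mean_i ||I_i||^2`` and ``eta' = 1``. Profiles come from
  the labeled association matrix I (rows for microbes, columns for
  drugs) and from the microbe-metabolite / drug-metabolite matrices.
* **Functional similarity**: for microbes, genome distance
  (``1 - d_mash``) and phylogeny (``1 - d_p / max d_p`` over patristic
  distances); for drugs, the Tanimoto coefficient over topological
  path fingerprints of their SMILES.

Aggregation is a two-level equal-weight mean: the GIP components are
averaged first, then averaged with the functional components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SimilarityError(ValueError):
    pass


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix over an ordered id list.

    ``components`` optionally retains the named per-aspect matrices
    that were averaged into ``values``.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.ids = tuple(self.ids)
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise SimilarityError(f"values shape {v.shape} != ({n}, {n})")
        if n and not np.allclose(v, v.T, atol=1e-12):
            raise SimilarityError("similarity matrix not symmetric")
        if n and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise SimilarityError("similarity entries outside [0, 1]")
        if n and not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise SimilarityError("similarity diagonal must be 1")
        self.values = np.clip(v, 0.0, 1.0)

    def max_offdiag(self, node_id: str) -> float:
        i = self.ids.index(node_id)
        row = np.delete(self.values[i], i)
        return float(row.max()) if row.size else 0.0

    def to_csv(self, path):
        pd.DataFrame(self.values, index=list(self.ids),
                     columns=list(self.ids)).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def gip_similarity(profile_matrix, ids, axis: str = "rows") -> SimilarityMatrix:
    """GIP kernel similarity between rows (or columns) of a binary matrix.

    The bandwidth is normalized by the mean squared profile norm over the
    selected axis; an all-zero matrix has no defined bandwidth and yields
    the identity (with a warning).
    """
    mat = np.asarray(profile_matrix, dtype=float)
    if axis == "cols":
        mat = mat.T
    elif axis != "rows":
        raise SimilarityError(f"axis must be 'rows' or 'cols', got {axis!r}")
    n = mat.shape[0]
    if n != len(ids):
        raise SimilarityError("profile count does not match id list")
    norm2 = (mat ** 2).sum(axis=1)
    mean_norm2 = norm2.mean() if n else 0.0
    if mean_norm2 == 0.0:
        logger.warning("GIP bandwidth undefined (all-zero profiles); returning identity")
        return SimilarityMatrix(ids, np.eye(n))
    eta = 1.0 / mean_norm2  # eta' = 1
    sq_dist = norm2[:, None] + norm2[None, :] - 2.0 * mat @ mat.T
    sq_dist = np.maximum(sq_dist, 0.0)
    vals = np.exp(-eta * sq_dist)
    np.fill_diagonal(vals, 1.0)
    vals = 0.5 * (vals + vals.T)
    return SimilarityMatrix(ids, vals)


# ---------------------------------------------------------------------------
# drug fingerprints

@dataclass
class FingerprintSet:
    """Per-drug set of on-bit positions from topological path fingerprints."""

    ids: tuple[str, ...]
    bitsets: dict[str, frozenset[int]]
    failed: tuple[str, ...] = ()  # unparsable SMILES, excluded from this component

    def __post_init__(self):
        for nid, bits in self.bitsets.items():
            if any(b < 0 for b in bits):
                raise SimilarityError(f"negative bit position for {nid}")
            if not bits:
                logger.warning("empty fingerprint for drug %s", nid)


def fingerprints_from_smiles(smiles_by_id: dict[str, str], n_bits: int = 2048) -> FingerprintSet:
    """RDKit topological path fingerprints from SMILES; failures recorded."""
    from rdkit import Chem, RDLogger
    RDLogger.DisableLog("rdApp.error")
    bitsets: dict[str, frozenset[int]] = {}
    failed: list[str] = []
    for nid, smi in smiles_by_id.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            failed.append(nid)
            continue
        fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
        bitsets[nid] = frozenset(fp.GetOnBits())
    if failed:
        logger.warning("unparsable SMILES for: %s", ", ".join(failed))
    ids = tuple(nid for nid in smiles_by_id if nid in bitsets)
    return FingerprintSet(ids, bitsets, tuple(failed))


def load_smiles_table(path) -> dict[str, str]:
    """Read a TSV of ``drug_id<TAB>smiles`` (header optional)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or parts[0].lower() in ("drug_id", "drug"):
                continue
            out[parts[0].strip()] = parts[1].strip()
    return out


def tanimoto_matrix(fps: FingerprintSet) -> SimilarityMatrix:
    """Pairwise Tanimoto coefficients ``|A & B| / |A | B|``.

    A pair with an empty union has similarity 1 on the diagonal
    (identical ids) and 0 otherwise.
    """
    ids = fps.ids
    n = len(ids)
    vals = np.zeros((n, n))
    for i in range(n):
        a = fps.bitsets[ids[i]]
        vals[i, i] = 1.0
        for j in range(i + 1, n):
            b = fps.bitsets[ids[j]]
            union = len(a | b)
            vals[i, j] = vals[j, i] = (len(a & b) / union) if union else 0.0
    return SimilarityMatrix(ids, vals)


# ---------------------------------------------------------------------------
# microbe functional similarity

@dataclass
class PhyloDistances:
    """Pairwise patristic (branch-path) distances between tree leaves."""

    ids: tuple[str, ...]
    dp: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.dp, dtype=float)
        if not np.allclose(d, d.T):
            raise SimilarityError("patristic distances not symmetric")
        if (d < 0).any() or not np.allclose(np.diag(d), 0):
            raise SimilarityError("patristic distances must be non-negative, zero diagonal")
        self.dp = d

    @property
    def max_dp(self) -> float:
        return float(self.dp.max())


def patristic_distances(newick: str) -> PhyloDistances:
    """Patristic distance matrix from a Newick string or file path.

    Missing branch lengths count as 0 (warned); duplicate leaf labels
    are an error.
    """
    import dendropy

    try:
        if "(" in newick:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        else:
            tree = dendropy.Tree.get(path=newick, schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise SimilarityError(f"duplicate leaf labels in tree: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise SimilarityError("duplicate leaf labels in tree")
    if len(labels) < 2:
        raise SimilarityError("tree must have at least 2 leaves")
    n_missing = sum(1 for e in tree.preorder_edge_iter()
                    if e.length is None and e.head_node is not tree.seed_node)
    if n_missing:
        logger.warning("%d branches missing lengths; treated as 0", n_missing)
        for e in tree.preorder_edge_iter():
            if e.length is None:
                e.length = 0.0
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: labels.index(t.label)
                  if t.label in labels else -1)
    taxa = [t for t in taxa if t.label in labels]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return PhyloDistances(tuple(t.label for t in taxa), d)


def phylo_similarity(newick: str) -> SimilarityMatrix:
    """Evolutionary similarity ``1 - d_p / max(d_p)`` from a Newick tree."""
    pd_ = patristic_distances(newick)
    if pd_.max_dp <= 0:
        raise SimilarityError("max patristic distance is 0; tree has no branch lengths")
    vals = 1.0 - pd_.dp / pd_.max_dp
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(pd_.ids, vals)


def genome_similarity(mash_csv) -> SimilarityMatrix:
    """Genomic similarity ``1 - d_mash`` from a precomputed distance CSV.

    Asymmetric inputs are symmetrized by averaging (with a warning);
    distances must lie in [0, 1].
    """
    df = pd.read_csv(mash_csv, index_col=0)
    d = df.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise SimilarityError("mash distance matrix must be square")
    if d.min() < 0 or d.max() > 1:
        raise SimilarityError("mash distances outside [0, 1]")
    if not np.allclose(d, d.T, atol=1e-12):
        logger.warning("asymmetric distance matrix; symmetrizing by averaging")
        d = 0.5 * (d + d.T)
    vals = 1.0 - d
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(tuple(str(c) for c in df.columns), vals)


# ---------------------------------------------------------------------------
# aggregation

def aggregate(components: list[SimilarityMatrix],
              weights: list[float] | None = None) -> SimilarityMatrix:
    """Weighted (default equal) mean of similarity matrices.

    All components must share one id list. Ids missing from a component
    (all-NaN rows allowed via ``np.nan``) fall back to the mean of the
    components that do cover them; coverage gaps are logged.
    """
    if not components:
        raise SimilarityError("no components to aggregate")
    ids = components[0].ids
    for c in components[1:]:
        if c.ids != ids:
            raise SimilarityError("components have mismatched id lists")
    if weights is None:
        weights = [1.0] * len(components)
    if len(weights) != len(components):
        raise SimilarityError("weights length mismatch")
    stack = np.stack([c.values for c in components])
    w = np.asarray(weights, dtype=float)[:, None, None]
    mask = ~np.isnan(stack)
    if not mask.all():
        logger.info("aggregate: %d entries missing from some component",
                    int((~mask).sum()))
    wsum = np.where(mask, w, 0.0).sum(axis=0)
    if (wsum == 0).any():
        raise SimilarityError("some entries covered by no component")
    vals = np.nansum(stack * w, axis=0) / wsum
    np.fill_diagonal(vals, 1.0)
    vals = 0.5 * (vals + vals.T)
    comp_map = {f"component_{k}": c.values for k, c in enumerate(components)}
    return SimilarityMatrix(ids, np.clip(vals, 0, 1), comp_map)


def microbe_similarity(assoc, sm_matrix, genomic: SimilarityMatrix | None = None,
                       evolutionary: SimilarityMatrix | None = None,
                       functional: SimilarityMatrix | None = None) -> SimilarityMatrix:
    """Two-level aggregate for microbes.

    GIP family = mean(GIP from association rows, GIP from SM rows);
    functional family = mean(genomic, evolutionary) or a pre-aggregated
    *functional* matrix. The two families are then averaged.
    """
    ids = assoc.microbes
    gip = aggregate([gip_similarity(assoc.values, ids, "rows"),
                     gip_similarity(sm_matrix, ids, "rows")])
    fam = [gip]
    if functional is not None:
        fam.append(functional)
    else:
        func = [m for m in (genomic, evolutionary) if m is not None]
        if func:
            fam.append(aggregate(func))
    return aggregate(fam)


def drug_similarity(assoc, dm_matrix, fingerprint: SimilarityMatrix | None = None,
                    functional: SimilarityMatrix | None = None) -> SimilarityMatrix:
    """Two-level aggregate for drugs: mean(mean(GIP_I, GIP_DM), fingerprint)."""
    ids = assoc.drugs
    gip = aggregate([gip_similarity(assoc.values, ids, "cols"),
                     gip_similarity(dm_matrix, ids, "rows")])
    fam = [gip]
    func = functional if functional is not None else fingerprint
    if func is not None:
        fam.append(func)
    return aggregate(fam)
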