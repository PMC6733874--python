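"""Hit-compound cheminformatics: Tanimoto clustering, guilt-by-association
target enrichment over ranked hit lists, and binding-panel normalization.

Enrichment is the generic enrichment-factor statistic: for a target with K
annotated compounds among N in the background, observing k annotated among
the top n ranked hits gives EF = (k/n)/(K/N), with a hypergeometric tail
p-value and an optional rank-permutation p-value, Benjamini-Hochberg
adjusted across targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError, MissingDataError


@dataclass
class CompoundRecord:
    """A compound: ID, binary fingerprint, optional annotations and Ki panel."""

    compound_id: str
    fingerprint: np.ndarray
    smiles: str | None = None
    targets: tuple[str, ...] = ()
    ki_panel_uM: dict[str, float] | None = None

    def __post_init__(self) -> None:
        fp = np.asarray(self.fingerprint).astype(bool)
        if fp.ndim != 1:
            raise InvalidInputError("fingerprint must be a 1-D bit vector")
        self.fingerprint = fp
        if self.ki_panel_uM is not None and any(k <= 0 for k in self.ki_panel_uM.values()):
            raise InvalidInputError("Ki values must be > 0")


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge history plus flat labels at the requested cut."""

    linkage_matrix: np.ndarray
    labels: np.ndarray
    n_clusters: int
    method: str = "average"


@dataclass(frozen=True)
class EnrichmentResult:
    target_id: str
    ef: float
    p_hypergeom: float
    q_value: float
    k_top: int
    k_background: int
    top_n: int
    background_n: int
    p_permutation: float | None = None


@dataclass
class BindingPanel:
    """Compound x receptor Ki matrix (unit recorded; default micromolar)."""

    ki: pd.DataFrame
    unit: str = "uM"

    def __post_init__(self) -> None:
        vals = self.ki.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise InvalidInputError("Ki values must be > 0")

    @property
    def npki(self) -> pd.DataFrame:
        return self.ki.apply(lambda col: npki(col.to_numpy(dtype=float)))


def tanimoto(a: np.ndarray, b: np.ndarray, *, empty_value: float = 1.0) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| between binary fingerprints.

    Two all-zero fingerprints are identical in their (empty) bit content, so
    the pair scores ``empty_value`` (default 1) with a warning; set
    ``empty_value=0`` for the conservative convention.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise InvalidInputError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints", stacklevel=2)
        return float(empty_value)
    return float(np.count_nonzero(a & b)) / union


def _fingerprint_matrix(library) -> tuple[np.ndarray, list[str]]:
    if isinstance(library, np.ndarray):
        fps = library.astype(bool)
        ids = [str(i) for i in range(fps.shape[0])]
        return fps, ids
    compounds = getattr(library, "compounds", library)
    fps = np.stack([c.fingerprint for c in compounds]).astype(bool)
    return fps, [c.compound_id for c in compounds]


def tanimoto_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity for a compounds x bits boolean matrix."""
    f = fps.astype(np.int64)
    inter = f @ f.T
    pop = f.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return sim


def cluster_hits(library, n_clusters: int) -> ClusterTree:
    """Average-linkage agglomerative clustering on 1 - Tanimoto distance.

    The tree is cut to exactly ``n_clusters`` flat labels.  Deterministic
    given input order (scipy resolves ties by smallest merge index).
    """
    fps, _ = _fingerprint_matrix(library)
    n = fps.shape[0]
    if n_clusters < 1:
        raise InvalidInputError("n_clusters must be >= 1")
    if n < n_clusters:
        raise InvalidInputError(f"need >= {n_clusters} compounds, got {n}")
    dist = 1.0 - tanimoto_matrix(fps)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return ClusterTree(linkage_matrix=z, labels=labels, n_clusters=n_clusters)


def _annotation_sets(annotations) -> dict[str, set[str]]:
    if isinstance(annotations, pd.DataFrame):
        out: dict[str, set[str]] = {}
        for target, grp in annotations.groupby("target_id"):
            out[str(target)] = set(grp["compound_id"].astype(str))
        return out
    return {str(t): set(map(str, cs)) for t, cs in annotations.items()}


def target_enrichment(
    ranked_compounds: Sequence[str],
    annotations,
    top_n: int,
    background: Iterable[str] | None = None,
    *,
    n_permutations: int = 0,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Per-target enrichment factors over the top of a ranked compound list.

    ``annotations`` is a (compound_id, target_id) table or a mapping
    target -> compound set.  EF compares the annotated fraction among the
    ``top_n`` ranked compounds to the background fraction; the p-value is the
    hypergeometric upper tail, optionally accompanied by a label-permutation
    p-value; q-values are Benjamini-Hochberg across targets.
    """
    ranked = [str(c) for c in ranked_compounds]
    if top_n < 1 or top_n > len(ranked):
        raise InvalidInputError("top_n must be within the ranked list length")
    bg = list(dict.fromkeys(map(str, background))) if background is not None else list(ranked)
    bg_set = set(bg)
    n_bg = len(bg)
    top = set(ranked[:top_n])
    per_target = _annotation_sets(annotations)
    rng = np.random.default_rng(seed)

    rows = []
    for target, annotated in sorted(per_target.items()):
        ann_bg = annotated & bg_set
        big_k = len(ann_bg)
        if big_k == 0:
            raise MissingDataError(f"target {target!r} has no annotated compound in the background")
        k = len(annotated & top)
        ef = (k / top_n) / (big_k / n_bg)
        p_hyp = float(hypergeom.sf(k - 1, n_bg, big_k, top_n))
        p_perm = None
        if n_permutations > 0:
            ann_mask = np.fromiter((c in ann_bg for c in bg), dtype=bool, count=n_bg)
            exceed = 0
            for _ in range(n_permutations):
                draw = rng.choice(n_bg, size=top_n, replace=False)
                if int(ann_mask[draw].sum()) >= k:
                    exceed += 1
            p_perm = (1 + exceed) / (n_permutations + 1)
        rows.append((target, ef, p_hyp, k, big_k, p_perm))

    _, q_values, _, _ = multipletests([r[2] for r in rows], method="fdr_bh")
    results = [
        EnrichmentResult(
            target_id=t,
            ef=ef,
            p_hypergeom=p,
            q_value=float(q),
            k_top=k,
            k_background=big_k,
            top_n=top_n,
            background_n=n_bg,
            p_permutation=p_perm,
        )
        for (t, ef, p, k, big_k, p_perm), q in zip(rows, q_values)
    ]
    results.sort(key=lambda r: (r.p_hypergeom, r.target_id))
    return results


def npki(ki):
    """Normalized binding affinity npKi = 4 + (-log10 Ki).

    Ki is taken in the panel's stated unit (micromolar by default); NaNs pass
    through for sparse panels.
    """
    arr = np.asarray(ki, dtype=float)
    finite = arr[~np.isnan(arr)]
    if np.any(finite <= 0):
        raise InvalidInputError("Ki must be > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 4.0 - np.log10(arr)
    if np.isscalar(ki) or arr.ndim == 0:
        return float(out)
    return out


def fingerprint_from_smiles(smiles: str, *, n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """2048-bit Morgan (circular) fingerprint from a SMILES string."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidInputError(f"could not parse SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype=np.uint8) == ord("1")
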