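"""Alignment of DNA samples to mRNA samples via eQTL-genotype classifiers.

For each tissue, probes with a very strong local eQTL (LOD > 100 at the grid
position nearest the probe) define classifiers that predict a sample's eQTL
genotype from its expression alone: a k-nearest-neighbor vote (k = 40,
Euclidean distance in 1–3 probe dimensions) that returns a genotype only when
strictly more than 80% of the neighbors agree, and missing otherwise.  The
observed eQTL genotype of a DNA sample is its multipoint genotype call at the
eQTL position (maximal posterior, required to exceed 0.99).

The proportion of matches between observed (DNA) and inferred (mRNA) eQTL
genotypes — pooled over eQTL and tissues — is the DNA-vs-mRNA similarity
matrix.  A correct sample matches itself at nearly 1; a mismatched pair
matches at about sum(f_g^2) ~ 0.375 under F2 genotype frequencies, so the
self/non-self distributions separate widely and mislabeled DNAs can be
relabeled with the same self/max/second rule used for the expression arrays.

One filter-and-refit pass is performed: samples whose own observed and
inferred genotypes match at < 0.7 are dropped from the training data and the
classifiers rederived, so badly mislabeled samples do not pollute training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .core_io import NA, ExpressionSet, GeneticMap, GenotypeTable, SimilarityMatrix, Diagnosis
from .expr_align import diagnose
from .genmap import PositionGrid, nearest_position
from .genoprob import GenoProbArray, calc_genoprob, call_genotype
from .qtlmap import hk_lod

logger = logging.getLogger("crossalign")


@dataclass
class EqtlUnit:
    """One local-eQTL location with its 1–3 associated probes."""

    chromosome: str
    grid_index: int
    position_cM: float
    probe_ids: list[str]
    lods: list[float]

    def __post_init__(self) -> None:
        if not 1 <= len(self.probe_ids) <= 3:
            raise ValueError("an eQTL unit carries 1-3 probes")


class EqtlGenotypeClassifier:
    """k-nearest-neighbor eQTL genotype classifier (sklearn-style).

    Parameters
    ----------
    k : int
        Number of neighbors (default 40).  When fewer training samples are
        available, all of them are used with the proportional vote rule and a
        warning.
    vote : float
        Required vote fraction in (0.5, 1]; a genotype is returned only when
        strictly more than ``vote * n_neighbors`` neighbors share it.

    Attributes (after :meth:`fit`)
    ------------------------------
    X_ : training expression values (m x d)
    y_ : training observed eQTL genotypes (int codes)
    sample_ids_ : training sample ids
    k_used_ : actual neighbor count
    """

    def __init__(self, k: int = 40, vote: float = 0.8):
        if not 0.5 < vote <= 1:
            raise ValueError(f"vote threshold must be in (0.5, 1], got {vote}")
        self.k = int(k)
        self.vote = float(vote)

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "vote": self.vote}

    def set_params(self, **params) -> "EqtlGenotypeClassifier":
        for key, val in params.items():
            if key not in ("k", "vote"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, val)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray, sample_ids: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        ok = np.isfinite(X).all(axis=1) & (y != NA)
        self.X_ = X[ok]
        self.y_ = y[ok].astype(np.int8)
        self.sample_ids_ = (
            [s for s, o in zip(sample_ids, ok) if o] if sample_ids is not None else None
        )
        m = len(self.y_)
        if m == 0:
            raise ValueError("no usable training samples")
        if m < self.k:
            warnings.warn(
                f"only {m} training samples for k={self.k}; using all with "
                "proportional voting",
                stacklevel=2,
            )
        self.k_used_ = min(self.k, m)
        self._nn = NearestNeighbors(n_neighbors=min(self.k_used_ + 1, m)).fit(self.X_)
        return self

    def predict(self, X: np.ndarray, exclude: np.ndarray | None = None) -> np.ndarray:
        """Predict genotypes for query points; NA where the vote fails.

        ``exclude[q]`` (optional) is the index of a training row to leave out
        of query q's neighbor set (-1 for none) — used so a sample never votes
        for itself.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        nq = X.shape[0]
        out = np.full(nq, NA, dtype=np.int8)
        usable = np.isfinite(X).all(axis=1)
        if not usable.any():
            return out
        _, idx = self._nn.kneighbors(X[usable])
        excl = np.full(nq, -1, dtype=int) if exclude is None else np.asarray(exclude, int)
        excl = excl[usable]
        for q_out, (row, ex) in zip(np.where(usable)[0], zip(idx, excl)):
            neigh = row[row != ex][: self.k_used_]
            counts = np.bincount(self.y_[neigh], minlength=3)
            top = int(counts.argmax())
            if counts[top] > self.vote * len(neigh):
                out[q_out] = top
        return out


def fit_knn(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: list[str] | None = None,
    k: int = 40,
    vote: float = 0.8,
) -> EqtlGenotypeClassifier:
    """Convenience wrapper: construct and fit an :class:`EqtlGenotypeClassifier`."""
    return EqtlGenotypeClassifier(k=k, vote=vote).fit(X, y, sample_ids)


def select_local_eqtl(
    es: ExpressionSet,
    probs: GenoProbArray,
    gmap: GeneticMap,
    lod_threshold: float = 100.0,
    max_probes_per_unit: int = 3,
) -> list[EqtlUnit]:
    """Probes with a strong local eQTL, grouped by shared grid position.

    Only autosomal probes with known location are considered; the LOD is a
    single Haley–Knott regression at the grid position nearest the probe, not
    a genome scan.  Probes sharing a grid position form one multi-probe unit
    (capped at ``max_probes_per_unit``, keeping the strongest).
    """
    shared = [s for s in es.sample_ids if s in set(probs.sample_ids)]
    es_idx = {s: i for i, s in enumerate(es.sample_ids)}
    pr_idx = {s: i for i, s in enumerate(probs.sample_ids)}
    rows_es = np.array([es_idx[s] for s in shared])
    rows_pr = np.array([pr_idx[s] for s in shared])

    hits: dict[tuple[str, int], list[tuple[float, str]]] = {}
    autosomes = set(probs.chromosomes())
    for j, (probe, chrom, pos) in enumerate(
        zip(es.probe_ids, es.probe_chrom, es.probe_pos)
    ):
        if chrom is None or not np.isfinite(pos) or chrom not in autosomes:
            continue
        k = nearest_position(probs.grid, chrom, float(pos))
        y = es.values[rows_es, j]
        p = probs.probs[chrom][rows_pr, k, :]
        lod = hk_lod(y, p)
        if lod > lod_threshold:
            hits.setdefault((chrom, k), []).append((lod, probe))

    units: list[EqtlUnit] = []
    for (chrom, k), plist in sorted(hits.items()):
        plist.sort(reverse=True)
        plist = plist[:max_probes_per_unit]
        units.append(
            EqtlUnit(
                chromosome=chrom,
                grid_index=k,
                position_cM=float(probs.grid.positions[chrom][k]),
                probe_ids=[p for _, p in plist],
                lods=[float(l) for l, _ in plist],
            )
        )
    if not units:
        logger.warning(
            "no local eQTL above LOD %.1f in tissue %s", lod_threshold, es.tissue
        )
    return units


def observed_eqtl_genotypes(
    calls: dict[str, np.ndarray], units: list[EqtlUnit]
) -> np.ndarray:
    """Observed (multipoint-call) genotype per DNA sample at each eQTL unit."""
    cols = [calls[u.chromosome][:, u.grid_index] for u in units]
    return np.stack(cols, axis=1) if cols else np.empty((0, 0), dtype=np.int8)


@dataclass
class TissueClassifiers:
    """Fitted per-eQTL classifiers for one tissue."""

    tissue: str
    units: list[EqtlUnit]
    classifiers: list[EqtlGenotypeClassifier]
    training_ids: list[str]  # DNA/mRNA shared ids offered for training
    k: int = 40
    vote: float = 0.8


def fit_tissue_classifiers(
    es: ExpressionSet,
    obs: np.ndarray,
    dna_ids: list[str],
    units: list[EqtlUnit],
    training_ids: list[str] | None = None,
    k: int = 40,
    vote: float = 0.8,
) -> TissueClassifiers:
    """Fit one k-NN classifier per eQTL unit from samples with both data types.

    ``obs`` is the DNA-side observed genotype matrix (len(dna_ids) x n_units).
    ``training_ids`` restricts training (used by the filter-and-refit pass);
    by default every sample present in both datasets is offered.
    """
    dna_idx = {s: i for i, s in enumerate(dna_ids)}
    es_idx = {s: i for i, s in enumerate(es.sample_ids)}
    if training_ids is None:
        training_ids = [s for s in es.sample_ids if s in dna_idx]
    rows_es = np.array([es_idx[s] for s in training_ids])
    rows_dna = np.array([dna_idx[s] for s in training_ids])
    classifiers = []
    for u_i, unit in enumerate(units):
        X = es.values[np.ix_(rows_es, es.probe_index(unit.probe_ids))]
        y = obs[rows_dna, u_i]
        classifiers.append(fit_knn(X, y, training_ids, k=k, vote=vote))
    return TissueClassifiers(
        tissue=es.tissue,
        units=units,
        classifiers=classifiers,
        training_ids=list(training_ids),
        k=k,
        vote=vote,
    )


def infer_eqtl_genotypes(tc: TissueClassifiers, es: ExpressionSet) -> np.ndarray:
    """Inferred eQTL genotype for every mRNA sample at every eQTL unit.

    A sample that is part of a classifier's training data is predicted with
    itself excluded from its own neighbor set, so a mislabeled sample cannot
    vote for its own (wrong) genotype.
    """
    n = es.n_samples
    out = np.full((n, len(tc.units)), NA, dtype=np.int8)
    for u_i, (unit, clf) in enumerate(zip(tc.units, tc.classifiers)):
        X = es.values[:, es.probe_index(unit.probe_ids)]
        exclude = np.full(n, -1, dtype=int)
        if clf.sample_ids_ is not None:
            train_pos = {s: i for i, s in enumerate(clf.sample_ids_)}
            for q, s in enumerate(es.sample_ids):
                exclude[q] = train_pos.get(s, -1)
        out[:, u_i] = clf.predict(X, exclude=exclude)
    return out


def match_proportion(observed: np.ndarray, inferred: np.ndarray) -> float:
    """Proportion of matching genotypes over positions where both are non-missing.

    NaN when there are no comparable positions.
    """
    observed = np.asarray(observed)
    inferred = np.asarray(inferred)
    if observed.shape != inferred.shape:
        raise ValueError("vectors must have equal length")
    comparable = (observed != NA) & (inferred != NA)
    n = int(comparable.sum())
    if n == 0:
        return float("nan")
    return float((observed[comparable] == inferred[comparable]).sum() / n)


def refit_after_filter(
    tc: TissueClassifiers,
    es: ExpressionSet,
    obs: np.ndarray,
    dna_ids: list[str],
    inferred: np.ndarray,
    min_match: float = 0.7,
) -> tuple[TissueClassifiers, list[str]]:
    """Drop training samples whose own observed/inferred match is < ``min_match``
    and refit the classifiers (the second and final pass).

    Returns the refitted classifiers and the ids that were removed.  Warns
    loudly when more than half the training samples are filtered, which
    suggests global mislabeling rather than isolated mix-ups.
    """
    dna_idx = {s: i for i, s in enumerate(dna_ids)}
    es_idx = {s: i for i, s in enumerate(es.sample_ids)}
    kept, removed = [], []
    for s in tc.training_ids:
        prop = match_proportion(obs[dna_idx[s]], inferred[es_idx[s]])
        if np.isnan(prop) or prop >= min_match:
            kept.append(s)
        else:
            removed.append(s)
    if removed and len(removed) > 0.5 * len(tc.training_ids):
        warnings.warn(
            f"{len(removed)}/{len(tc.training_ids)} samples filtered in "
            f"{tc.tissue}: possible global mislabeling",
            stacklevel=2,
        )
    refit = fit_tissue_classifiers(
        es, obs, dna_ids, tc.units, training_ids=kept, k=tc.k, vote=tc.vote
    )
    return refit, removed


def _match_counts(O: np.ndarray, I: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(matches, comparable) count matrices between DNA rows and mRNA rows."""
    valid_o = (O != NA).astype(float)
    valid_i = (I != NA).astype(float)
    matches = np.zeros((O.shape[0], I.shape[0]))
    for g in (0, 1, 2):
        matches += (O == g).astype(float) @ (I == g).astype(float).T
    comparable = valid_o @ valid_i.T
    return matches, comparable


def dna_mrna_similarity(
    observed: np.ndarray,
    dna_ids: list[str],
    inferred_by_tissue: dict[str, tuple[np.ndarray, list[str]]],
    unit_slices: dict[str, slice],
) -> tuple[dict[str, SimilarityMatrix], SimilarityMatrix]:
    """Per-tissue and combined DNA-vs-mRNA similarity matrices.

    ``observed`` holds all eQTL columns (all tissues concatenated); per tissue,
    ``unit_slices[t]`` selects that tissue's columns and
    ``inferred_by_tissue[t]`` is (inferred matrix, mRNA sample ids).  The
    combined matrix pools matches and comparisons across tissues (a pooled
    proportion, not a mean of per-tissue proportions); a cell with no
    comparable genotypes anywhere is missing.
    """
    col_ids = list(
        dict.fromkeys(s for _, ids in inferred_by_tissue.values() for s in ids)
    )
    col_pos = {s: k for k, s in enumerate(col_ids)}
    total_m = np.zeros((len(dna_ids), len(col_ids)))
    total_c = np.zeros_like(total_m)
    per_tissue: dict[str, SimilarityMatrix] = {}
    for tissue, (inf, mrna_ids) in inferred_by_tissue.items():
        O = observed[:, unit_slices[tissue]]
        m, c = _match_counts(O, inf)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = m / c
        vals[c == 0] = np.nan
        per_tissue[tissue] = SimilarityMatrix(
            row_ids=list(dna_ids),
            col_ids=list(mrna_ids),
            values=vals,
            score_kind="match_proportion",
        )
        idx = [col_pos[s] for s in mrna_ids]
        total_m[:, idx] += m
        total_c[:, idx] += c
    with np.errstate(invalid="ignore", divide="ignore"):
        combined_vals = total_m / total_c
    combined_vals[total_c == 0] = np.nan
    combined = SimilarityMatrix(
        row_ids=list(dna_ids),
        col_ids=col_ids,
        values=combined_vals,
        score_kind="match_proportion",
    )
    return per_tissue, combined


def diagnose_dna(
    combined: SimilarityMatrix,
    self_threshold: float = 0.8,
    match_threshold: float = 0.8,
    margin: float = 0.1,
) -> Diagnosis:
    """Self/max/second decision rule on the combined match-proportion matrix.

    Same rule as the expression-side diagnosis, with thresholds on the
    match-proportion scale; two DNA rows pointing at the same mRNA label are
    resolved as a duplicate when the target's own row is correct.
    """
    return diagnose(combined, self_threshold, match_threshold, margin)


@dataclass
class GenoAlignResult:
    """Everything the DNA-vs-mRNA alignment pass produced.

    ``observed`` holds the multipoint genotype calls of every DNA sample at
    every eQTL unit (tissues concatenated; ``unit_slices`` maps each tissue to
    its columns); ``inferred`` the per-tissue classifier predictions with
    their mRNA sample ids.
    """

    units: dict[str, list[EqtlUnit]]
    per_tissue: dict[str, SimilarityMatrix]
    combined: SimilarityMatrix
    diagnosis: Diagnosis
    filtered_samples: dict[str, list[str]]
    observed: np.ndarray = field(repr=False, default=None)
    inferred: dict[str, tuple[np.ndarray, list[str]]] = field(repr=False, default=None)
    unit_slices: dict[str, slice] = field(repr=False, default=None)
    genoprobs: GenoProbArray = field(repr=False, default=None)


def align_genotypes(
    expr_sets: dict[str, ExpressionSet],
    gt: GenotypeTable,
    gmap: GeneticMap,
    grid: PositionGrid,
    epsilon: float = 0.002,
    map_function: str = "carter_falconer",
    lod_threshold: float = 100.0,
    call_threshold: float = 0.99,
    k: int = 40,
    vote: float = 0.8,
    min_match: float = 0.7,
    self_threshold: float = 0.8,
    match_threshold: float = 0.8,
    margin: float = 0.1,
    genoprobs: GenoProbArray | None = None,
) -> GenoAlignResult:
    """Run the full DNA-vs-mRNA alignment: genotype probabilities, local-eQTL
    selection, classifier fit, filter-and-refit, pooled similarity, diagnosis.

    Expression-side corrections should be applied before calling this, mirroring
    the study order (arrays first, then genotypes).
    """
    if genoprobs is None:
        genoprobs = calc_genoprob(gt, gmap, grid, epsilon, map_function)
    calls = call_genotype(genoprobs, call_threshold)

    units: dict[str, list[EqtlUnit]] = {}
    obs_blocks: list[np.ndarray] = []
    unit_slices: dict[str, slice] = {}
    inferred: dict[str, tuple[np.ndarray, list[str]]] = {}
    filtered: dict[str, list[str]] = {}
    offset = 0
    for tissue, es in expr_sets.items():
        u = select_local_eqtl(es, genoprobs, gmap, lod_threshold)
        units[tissue] = u
        obs = observed_eqtl_genotypes(calls, u)
        obs_blocks.append(obs)
        unit_slices[tissue] = slice(offset, offset + len(u))
        offset += len(u)
        if not u:
            inferred[tissue] = (np.empty((es.n_samples, 0), dtype=np.int8), list(es.sample_ids))
            filtered[tissue] = []
            continue
        tc = fit_tissue_classifiers(es, obs, gt.sample_ids, u, k=k, vote=vote)
        inf1 = infer_eqtl_genotypes(tc, es)
        tc2, removed = refit_after_filter(tc, es, obs, gt.sample_ids, inf1, min_match)
        filtered[tissue] = removed
        inferred[tissue] = (infer_eqtl_genotypes(tc2, es), list(es.sample_ids))
        logger.info(
            "tissue %s: %d eQTL units, %d training samples filtered",
            tissue,
            len(u),
            len(removed),
        )

    observed = (
        np.concatenate(obs_blocks, axis=1)
        if obs_blocks
        else np.empty((gt.n_samples, 0), dtype=np.int8)
    )
    per_tissue, combined = dna_mrna_similarity(
        observed, gt.sample_ids, inferred, unit_slices
    )
    diag = diagnose_dna(combined, self_threshold, match_threshold, margin)
    return GenoAlignResult(
        units=units,
        per_tissue=per_tissue,
        combined=combined,
        diagnosis=diag,
        filtered_samples=filtered,
        observed=observed,
        inferred=inferred,
        unit_slices=unit_slices,
        genoprobs=genoprobs,
    )


def apply_genotype_corrections(
    gt: GenotypeTable, diagnosis: Diagnosis
) -> tuple[GenotypeTable, list[dict]]:
    """Relabel mislabeled DNA rows per the diagnosis; drop duplicate rows.

    Relabels are applied simultaneously (cycles and chains both work); a label
    vacated by a chain simply disappears.  Duplicate rows are dropped (their
    DNA belongs to a sample that already has a correct row).  Unfixable and
    unverifiable rows are kept and flagged — unless an unfixable row's label
    is claimed by a relabel, in which case that row is dropped: its label is
    known to be wrong and now belongs to the relabeled row.
    """
    relabel = diagnosis.relabel_map()
    targets = list(relabel.values())
    if len(set(targets)) != len(targets):
        clash = sorted({t for t in targets if targets.count(t) > 1})
        raise ValueError(f"conflicting DNA relabels: multiple rows claim {clash}")
    ids = list(gt.sample_ids)
    orig_index = {s: k for k, s in enumerate(ids)}
    changelog: list[dict] = []
    drop: set[int] = set()
    for _, row in diagnosis.rows_with_status("duplicate").iterrows():
        drop.add(orig_index[row["label"]])
        changelog.append(
            dict(action="drop_duplicate", from_label=row["label"], to_label=row["inferred_label"])
        )
    for src, dst in relabel.items():
        ids[orig_index[src]] = dst
        changelog.append(dict(action="relabel", from_label=src, to_label=dst))
    claimed = set(targets)
    for status in ("unfixable", "unverifiable"):
        for _, row in diagnosis.rows_with_status(status).iterrows():
            if status == "unfixable" and row["label"] in claimed:
                drop.add(orig_index[row["label"]])
                changelog.append(
                    dict(action="drop_unfixable_label_claimed", from_label=row["label"], to_label=None)
                )
            else:
                changelog.append(dict(action=f"flag_{status}", from_label=row["label"], to_label=None))
    keep = [kk for kk in range(len(ids)) if kk not in drop]
    new_ids = [ids[kk] for kk in keep]
    if len(set(new_ids)) != len(new_ids):
        raise ValueError("DNA relabeling produced duplicate sample ids")
    corrected = GenotypeTable(
        sample_ids=new_ids,
        sex=[gt.sex[kk] for kk in keep],
        calls=gt.calls[keep],
        markers=list(gt.markers),
    )
    return corrected, changelog
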