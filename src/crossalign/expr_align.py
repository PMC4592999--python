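"""Alignment of expression arrays across tissues: mix-up detection and correction.

The scheme: for each tissue pair, find the probes whose expression is highly
correlated between the tissues (the tissue-shared signal); across those probes,
correlate every sample in one tissue with every sample in the other.  A
correctly labeled sample is most similar to itself; a mislabeled array is most
similar to the sample it really came from.  Per-tissue similarity is the
median over the tissue pairs involving that tissue, and the diagnosis rule
compares the self similarity, the row maximum and the second-highest value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Diagnosis, ExpressionSet, SimilarityMatrix

logger = logging.getLogger("crossalign")


@dataclass
class TissuePairProbes:
    """Probes shared by a tissue pair whose between-tissue correlation exceeds
    the selection threshold."""

    tissue_s: str
    tissue_t: str
    probe_ids: list[str]
    correlations: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.correlations = np.asarray(self.correlations, dtype=float)
        if np.any(self.correlations <= self.threshold):
            raise ValueError("stored correlations must exceed the selection threshold")


def _rank_rows(a: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, NaNs preserved (for Spearman correlation)."""
    out = np.full(a.shape, np.nan)
    for i in range(a.shape[0]):
        obs = np.isfinite(a[i])
        if obs.any():
            out[i, obs] = stats.rankdata(a[i, obs], method="average")
    return out


def nan_cross_correlation(X: np.ndarray, Y: np.ndarray, min_obs: int = 3) -> np.ndarray:
    """Pearson correlation between every row of ``X`` and every row of ``Y``
    over pairwise-complete columns.

    Fully vectorized with mask algebra; cells with fewer than ``min_obs``
    complete pairs, or zero variance in either vector, are NaN.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    mx = np.isfinite(X)
    my = np.isfinite(Y)
    X0 = np.where(mx, X, 0.0)
    Y0 = np.where(my, Y, 0.0)
    fx = mx.astype(float)
    fy = my.astype(float)
    n = fx @ fy.T
    sx = X0 @ fy.T
    sy = fx @ Y0.T
    sxx = (X0 * X0) @ fy.T
    syy = fx @ (Y0 * Y0).T
    sxy = X0 @ Y0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r = cov / np.sqrt(varx * vary)
    r[n < min_obs] = np.nan
    return np.clip(r, -1.0, 1.0)


def select_corr_probes(
    es: ExpressionSet,
    et: ExpressionSet,
    threshold: float = 0.75,
    method: str = "pearson",
) -> TissuePairProbes:
    """Select the probes correlated above ``threshold`` between two tissues.

    For each probe present in both tissues, the correlation is computed across
    the samples assayed in both, omitting samples missing that probe in either
    tissue; probes that are constant in either tissue have undefined
    correlation and are excluded.
    """
    common_probes = [p for p in es.probe_ids if p in set(et.probe_ids)]
    common_samples = [s for s in es.sample_ids if s in set(et.sample_ids)]
    if len(common_samples) < 3:
        raise ValueError(
            f"only {len(common_samples)} samples assayed in both "
            f"{es.tissue} and {et.tissue}; need at least 3"
        )
    si = [es.sample_ids.index(s) for s in common_samples]
    ti = [et.sample_ids.index(s) for s in common_samples]
    A = es.values[np.ix_(si, es.probe_index(common_probes))]
    B = et.values[np.ix_(ti, et.probe_index(common_probes))]
    if method == "spearman":
        A = _rank_rows(A.T).T
        B = _rank_rows(B.T).T
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    # per-probe correlation = diagonal of the cross-correlation of columns
    r = np.array(
        [nan_cross_correlation(A[:, [j]].T, B[:, [j]].T)[0, 0] for j in range(A.shape[1])]
    )
    keep = np.isfinite(r) & (r > threshold)
    return TissuePairProbes(
        tissue_s=es.tissue,
        tissue_t=et.tissue,
        probe_ids=[p for p, k in zip(common_probes, keep) if k],
        correlations=r[keep],
        threshold=threshold,
    )


def pair_similarity(
    es: ExpressionSet,
    et: ExpressionSet,
    probes: TissuePairProbes,
    min_probes: int = 20,
    method: str = "pearson",
) -> SimilarityMatrix:
    """Between-sample correlation matrix across the selected probes.

    Cell (i, j) correlates sample i's expression in tissue ``s`` with sample
    j's in tissue ``t`` across the selected probes; rows are tissue-s samples,
    columns tissue-t samples.
    """
    if len(probes.probe_ids) < min_probes:
        raise ValueError(
            f"only {len(probes.probe_ids)} probes selected for "
            f"({probes.tissue_s}, {probes.tissue_t}); lower the correlation "
            f"threshold or min_probes (currently {min_probes})"
        )
    X = es.values[:, es.probe_index(probes.probe_ids)]
    Y = et.values[:, et.probe_index(probes.probe_ids)]
    if method == "spearman":
        X = _rank_rows(X)
        Y = _rank_rows(Y)
    r = nan_cross_correlation(X, Y)
    return SimilarityMatrix(
        row_ids=list(es.sample_ids),
        col_ids=list(et.sample_ids),
        values=r,
        score_kind="correlation",
    )


def tissue_similarity(pair_matrices: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Median similarity across the tissue pairs involving one target tissue.

    All input matrices must share their row tissue (the target); columns are
    aligned on the union of column labels, and each cell is the median over
    the pairs where it is non-missing.
    """
    if not pair_matrices:
        raise ValueError("need at least one pair matrix")
    row_ids = pair_matrices[0].row_ids
    for m in pair_matrices[1:]:
        if m.row_ids != row_ids:
            raise ValueError("pair matrices have mismatched row samples")
    col_ids = list(dict.fromkeys(c for m in pair_matrices for c in m.col_ids))
    col_pos = {c: k for k, c in enumerate(col_ids)}
    stacked = np.full((len(pair_matrices), len(row_ids), len(col_ids)), np.nan)
    for a, m in enumerate(pair_matrices):
        idx = [col_pos[c] for c in m.col_ids]
        stacked[a][:, idx] = m.values
    with np.errstate(all="ignore"):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(stacked, axis=0)
    return SimilarityMatrix(
        row_ids=list(row_ids), col_ids=col_ids, values=med, score_kind="correlation"
    )


def diagnose(
    sim: SimilarityMatrix,
    self_threshold: float = 0.75,
    match_threshold: float = 0.8,
    margin: float = 0.1,
) -> Diagnosis:
    """Apply the self/max/second decision rule to a similarity matrix.

    Per row: ``correct`` when the self similarity equals the row maximum;
    ``relabel`` to the argmax label when the self similarity is observed and
    small (< ``self_threshold``), the maximum is large (> ``match_threshold``)
    and clearly separated from the second-highest value (difference >
    ``margin``); ``unfixable`` when the self similarity is present but not
    maximal and no confident relabel exists; ``unverifiable`` when the self
    similarity is missing.

    Rows with a missing self similarity (the sample was never assayed on the
    other side) are never auto-relabeled, however strong their best match:
    with no self cell to contradict, a chance near-identity between unrelated
    samples would be indistinguishable from a real mix-up, and such samples
    belong in the cannot-be-verified class.  Their best-match evidence is
    still recorded in the report.

    A relabel whose target label is itself a correct row is reported as
    ``duplicate`` of that target (two assays of the same sample).
    """
    col_pos = {c: k for k, c in enumerate(sim.col_ids)}
    records = []
    for i, label in enumerate(sim.row_ids):
        row = sim.values[i]
        self_score = row[col_pos[label]] if label in col_pos else np.nan
        finite = np.isfinite(row)
        if not finite.any():
            records.append(
                dict(
                    label=label,
                    status="unverifiable",
                    inferred_label=None,
                    self_score=np.nan,
                    max_score=np.nan,
                    argmax_label=None,
                    second_score=np.nan,
                )
            )
            continue
        order = np.argsort(np.where(finite, row, -np.inf))[::-1]
        max_idx = int(order[0])
        max_score = float(row[max_idx])
        argmax_label = sim.col_ids[max_idx]
        second_score = float(row[order[1]]) if finite.sum() > 1 else np.nan
        # prefer the self cell on exact ties with the maximum
        self_is_max = np.isfinite(self_score) and self_score >= max_score
        confident_match = (
            argmax_label != label
            and max_score > match_threshold
            and (not np.isfinite(second_score) or max_score - second_score > margin)
        )
        if self_is_max:
            status, inferred = "correct", None
            argmax_label = label
        elif not np.isfinite(self_score):
            status, inferred = "unverifiable", None
        elif self_score < self_threshold and confident_match:
            status, inferred = "relabel", argmax_label
        else:
            status, inferred = "unfixable", None
        records.append(
            dict(
                label=label,
                status=status,
                inferred_label=inferred,
                self_score=float(self_score) if np.isfinite(self_score) else np.nan,
                max_score=max_score,
                argmax_label=argmax_label,
                second_score=second_score,
            )
        )
    df = pd.DataFrame.from_records(records)

    # relabels pointing at a row that is itself correct are sample duplicates
    correct_labels = set(df.loc[df["status"] == "correct", "label"])
    dup = (df["status"] == "relabel") & df["inferred_label"].isin(correct_labels)
    df.loc[dup, "status"] = "duplicate"
    return Diagnosis(df)


def find_within_tissue_duplicates(
    es: ExpressionSet,
    probe_ids: list[str],
    dup_threshold: float = 0.9,
) -> list[tuple[str, str, float]]:
    """Within-tissue sample pairs correlated above ``dup_threshold`` across the
    chosen probe subset (candidates for unintended technical replicates)."""
    if len(probe_ids) < 3:
        raise ValueError("need at least 3 probes for duplicate screening")
    X = es.values[:, es.probe_index(probe_ids)]
    r = nan_cross_correlation(X, X)
    out = []
    n = len(es.sample_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(r[i, j]) and r[i, j] > dup_threshold:
                out.append((es.sample_ids[i], es.sample_ids[j], float(r[i, j])))
    return out


def apply_corrections(
    expr_sets: dict[str, ExpressionSet],
    diagnoses: dict[str, Diagnosis],
    drop_unfixable: bool = True,
) -> tuple[dict[str, ExpressionSet], list[dict]]:
    """Apply per-tissue diagnoses: relabel mix-ups (swaps and k-cycles),
    combine duplicates by per-probe mean, drop unfixable arrays.

    ``drop_unfixable=False`` keeps unfixable rows — used for the first pass of
    an iterated alignment, where a row's low self-similarity may be caused by
    a (fixable) mix-up in a different tissue rather than by its own array.
    Two rows relabeling to the same target within one tissue is a conflict and
    raises.  Returns corrected sets plus a change log.
    """
    corrected: dict[str, ExpressionSet] = {}
    changelog: list[dict] = []
    for tissue, es in expr_sets.items():
        d = diagnoses.get(tissue)
        if d is None:
            corrected[tissue] = es.copy()
            continue
        relabel = d.relabel_map()
        targets = list(relabel.values())
        if len(set(targets)) != len(targets):
            clash = sorted({t for t in targets if targets.count(t) > 1})
            raise ValueError(f"conflicting relabels in {tissue}: multiple rows claim {clash}")
        new_es = es.copy()
        values = new_es.values
        orig_index = {s: k for k, s in enumerate(es.sample_ids)}
        ids = list(new_es.sample_ids)
        drop: set[int] = set()

        for _, row in d.rows_with_status("duplicate").iterrows():
            i = orig_index[row["label"]]
            target = row["inferred_label"]
            if target in orig_index:
                j = orig_index[target]
                values[j] = np.nanmean(np.stack([values[i], values[j]]), axis=0)
                drop.add(i)
                changelog.append(
                    dict(tissue=tissue, action="combine_duplicate", from_label=row["label"], to_label=target)
                )
            else:  # duplicate of a sample with no array here: just relabel
                ids[i] = target
                changelog.append(
                    dict(tissue=tissue, action="relabel", from_label=row["label"], to_label=target)
                )

        for src, dst in relabel.items():  # simultaneous rename, so cycles work
            ids[orig_index[src]] = dst
            changelog.append(
                dict(tissue=tissue, action="relabel", from_label=src, to_label=dst)
            )

        if drop_unfixable:
            for _, row in d.rows_with_status("unfixable").iterrows():
                drop.add(orig_index[row["label"]])
                changelog.append(
                    dict(tissue=tissue, action="drop_unfixable", from_label=row["label"], to_label=None)
                )

        keep = [k for k in range(len(ids)) if k not in drop]
        if len(set(ids[k] for k in keep)) != len(keep):
            raise ValueError(f"relabeling in {tissue} produced duplicate sample ids")
        corrected[tissue] = ExpressionSet(
            tissue=tissue,
            sample_ids=[ids[k] for k in keep],
            values=values[keep],
            probe_ids=list(new_es.probe_ids),
            probe_chrom=list(new_es.probe_chrom),
            probe_pos=new_es.probe_pos.copy(),
        )
    return corrected, changelog


def merge_diagnoses(first: Diagnosis, second: Diagnosis) -> Diagnosis:
    """Combine a first-pass diagnosis with the re-diagnosis after corrections.

    Rows the first pass acted on (relabel/duplicate) keep their first-pass
    verdict and evidence — they describe what was wrong with the original
    data.  Rows the first pass could not resolve (unfixable/unverifiable) take
    the second pass's verdict: if their low self-similarity was collateral
    damage from a mix-up in another tissue, they re-diagnose as correct once
    that mix-up is fixed.
    """
    merged = first.table.copy()
    by_label = {row["label"]: row for _, row in second.table.iterrows()}
    for i, row in merged.iterrows():
        if row["status"] in ("unfixable", "unverifiable") and row["label"] in by_label:
            merged.loc[i] = by_label[row["label"]]
    return Diagnosis(merged)


def align_expression(
    expr_sets: dict[str, ExpressionSet],
    corr_threshold: float = 0.75,
    min_probes: int = 20,
    self_threshold: float = 0.75,
    match_threshold: float = 0.8,
    margin: float = 0.1,
    dup_threshold: float = 0.9,
    method: str = "pearson",
) -> tuple[dict[str, Diagnosis], dict[str, SimilarityMatrix], dict[str, list]]:
    """Run the full cross-tissue alignment pass.

    Returns per-tissue diagnoses, per-tissue median similarity matrices, and
    per-tissue within-tissue duplicate candidate lists.
    """
    tissues = list(expr_sets)
    if len(tissues) < 2:
        raise ValueError("need at least two tissues to align expression arrays")
    pair_probes: dict[tuple[str, str], TissuePairProbes] = {}
    pair_mats: dict[tuple[str, str], SimilarityMatrix] = {}
    for a, s in enumerate(tissues):
        for t in tissues[a + 1 :]:
            pp = select_corr_probes(expr_sets[s], expr_sets[t], corr_threshold, method)
            pair_probes[(s, t)] = pp
            logger.info("tissue pair (%s, %s): %d probes selected", s, t, len(pp.probe_ids))

    diagnoses: dict[str, Diagnosis] = {}
    similarities: dict[str, SimilarityMatrix] = {}
    duplicates: dict[str, list] = {}
    for s in tissues:
        mats = []
        union_probes: list[str] = []
        for t in tissues:
            if t == s:
                continue
            key = (s, t) if (s, t) in pair_probes else (t, s)
            pp = pair_probes[key]
            if pp.tissue_s == s:
                mats.append(pair_similarity(expr_sets[s], expr_sets[t], pp, min_probes, method))
            else:
                flipped = TissuePairProbes(s, t, pp.probe_ids, pp.correlations, pp.threshold)
                mats.append(pair_similarity(expr_sets[s], expr_sets[t], flipped, min_probes, method))
            union_probes.extend(pp.probe_ids)
        sim = tissue_similarity(mats)
        similarities[s] = sim
        diagnoses[s] = diagnose(sim, self_threshold, match_threshold, margin)
        union_probes = list(dict.fromkeys(p for p in union_probes if p in set(expr_sets[s].probe_ids)))
        duplicates[s] = find_within_tissue_duplicates(expr_sets[s], union_probes, dup_threshold)
    return diagnoses, similarities, duplicates
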