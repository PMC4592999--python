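"""Genotype-level quality control and plate-geometry classification of DNA errors.

Covers the screens that first reveal sample problems in an intercross:
duplicate DNA samples (near-identical genotype rows), sex vs. X-chromosome
concordance (an F2 female from a BTBR-dam cross should be RR or BR on the X;
a male, hemizygous, is coded BB or RR), per-sample genotype behavior metrics
(missing rate, homozygosity, apparent crossover count), and — once mislabeled
DNAs have been diagnosed — classification of each relabel by its displacement
in 96-well plate filling order (off-by-one / off-by-two pipetting errors,
longer same-plate moves, cross-plate moves), including maximal runs of
consecutive equal offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import NA, Diagnosis, GeneticMap, GenotypeTable, PlateLayout
from .genoprob import GenoProbArray

logger = logging.getLogger("crossalign")


def find_duplicate_dna(
    gt: GenotypeTable,
    identity_threshold: float = 0.98,
    min_shared_markers: int = 50,
) -> list[tuple[str, str, float]]:
    """Unordered sample pairs with genotype identity above ``identity_threshold``.

    Identity = identical non-missing calls / jointly non-missing markers.
    Pairs with fewer than ``min_shared_markers`` jointly typed markers are
    excluded with a warning.  Independent F2 samples are expected near
    sum(f_g^2) ~ 0.375, far below the default threshold.
    """
    calls = gt.calls
    valid = (calls != NA).astype(float)
    shared = valid @ valid.T
    matches = np.zeros_like(shared)
    for g in (0, 1, 2):
        m = (calls == g).astype(float)
        matches += m @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = matches / shared
    out = []
    n = gt.n_samples
    skipped = 0
    for i in range(n):
        for j in range(i + 1, n):
            if shared[i, j] < min_shared_markers:
                skipped += 1
                continue
            if identity[i, j] > identity_threshold:
                out.append((gt.sample_ids[i], gt.sample_ids[j], float(identity[i, j])))
    if skipped:
        logger.warning(
            "find_duplicate_dna: %d pairs with <%d jointly typed markers excluded",
            skipped,
            min_shared_markers,
        )
    return out


def check_sex_vs_x(
    gt: GenotypeTable, gmap: GeneticMap, min_discordant: int = 2
) -> pd.DataFrame:
    """Per-sample X-chromosome / recorded-sex concordance report.

    Females should carry only RR or BR on the X (BB calls are discordant);
    males, hemizygous and stored as homozygous, should carry no BR calls.
    A sample is flagged sex-discordant when its discordant-call count reaches
    ``min_discordant``; exactly one discordant call is reported as a probable
    genotyping error instead.  Samples of unknown sex are skipped (listed with
    a ``skipped`` flag).
    """
    x_markers = [
        j for j, m in enumerate(gt.markers)
        if gmap.chromosomes[gmap.markers.index(m)] in gmap.x_chromosomes
    ]
    if not x_markers:
        raise ValueError("no X-linked markers in the map")
    xcalls = gt.calls[:, x_markers]
    records = []
    for i, (sid, sex) in enumerate(zip(gt.sample_ids, gt.sex)):
        if sex == "unknown":
            records.append(
                dict(sample=sid, sex=sex, n_discordant=0, flag="skipped")
            )
            continue
        row = xcalls[i]
        discordant = int((row == 0).sum()) if sex == "female" else int((row == 1).sum())
        if discordant >= min_discordant:
            flag = "sex_discordant"
        elif discordant == 1:
            flag = "probable_genotyping_error"
        else:
            flag = "ok"
        records.append(dict(sample=sid, sex=sex, n_discordant=discordant, flag=flag))
    return pd.DataFrame.from_records(records)


@dataclass
class QcReport:
    """Per-sample genotype-behavior metrics with robust outlier flags."""

    table: pd.DataFrame  # sample, missing_rate, prop_homozygous, n_crossovers, flags


def _robust_cutoff(x: np.ndarray, k: float = 5.0) -> float:
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med + k * mad


def genotype_qc(
    gt: GenotypeTable, probs: GenoProbArray, mad_k: float = 5.0
) -> QcReport:
    """Per-sample missing rate, autosomal homozygosity, and apparent crossovers.

    The crossover count is the number of genotype-state changes in the
    argmax-posterior path at the typed marker positions, summed over
    autosomes.  Samples beyond median + ``mad_k`` * MAD on any metric (or with
    everything missing) are flagged.
    """
    n = gt.n_samples
    missing_rate = (gt.calls == NA).mean(axis=1)

    homo = np.zeros(n)
    n_calls = np.zeros(n)
    xovers = np.zeros(n, dtype=int)
    for chrom in probs.chromosomes():
        marker_mask = probs.grid.marker_mask(chrom)
        post = probs.probs[chrom][:, marker_mask, :]
        path = post.argmax(axis=2)
        xovers += (np.diff(path, axis=1) != 0).sum(axis=1)
        # homozygosity from the observed calls at this chromosome's markers;
        # grid.marker_index indexes the map's marker list, which matches the
        # genotype table's column order
        midx = probs.grid.marker_index[chrom][marker_mask]
        calls = gt.calls[:, midx]
        obs = calls != NA
        homo += ((calls == 0) | (calls == 2)).sum(axis=1)
        n_calls += obs.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        prop_homo = homo / n_calls
    flags = []
    miss_cut = _robust_cutoff(missing_rate, mad_k)
    homo_cut = _robust_cutoff(prop_homo[np.isfinite(prop_homo)], mad_k)
    xo_cut = _robust_cutoff(xovers.astype(float), mad_k)
    for i in range(n):
        f = []
        if missing_rate[i] >= 1.0:
            f.append("all_missing")
        elif missing_rate[i] > miss_cut:
            f.append("high_missing")
        if np.isfinite(prop_homo[i]) and prop_homo[i] > homo_cut:
            f.append("high_homozygosity")
        if xovers[i] > xo_cut:
            f.append("excess_crossovers")
        flags.append(";".join(f) if f else "ok")
    table = pd.DataFrame(
        dict(
            sample=gt.sample_ids,
            missing_rate=missing_rate,
            prop_homozygous=prop_homo,
            n_crossovers=xovers,
            flag=flags,
        )
    )
    return QcReport(table)


def classify_plate_errors(
    diagnosis: Diagnosis,
    layout: PlateLayout,
    order: str = "column-major",
) -> pd.DataFrame:
    """Categorize each diagnosed relabel/duplicate by plate-geometry offset.

    For each mislabeled row, the signed offset is (filling-order position
    where the sample was found) - (position where it belonged), i.e. the
    position of the row's current label minus the position of its inferred
    true label.  |offset| of 1 or 2 on the same plate are the off-by-one /
    off-by-two pipetting signatures; anything larger on the same plate is
    long-range; different plates is cross-plate.  The report also carries
    maximal runs of consecutive equal offsets (``run_id``/``run_length``).
    """
    fill = layout.fill_positions(order)
    plate_of = dict(zip(layout.samples, layout.plates))
    rows = diagnosis.rows_with_status("relabel", "duplicate")
    records = []
    for _, row in rows.iterrows():
        found_label, true_label = row["label"], row["inferred_label"]
        if found_label not in fill or true_label not in fill:
            records.append(
                dict(
                    label=found_label,
                    true_label=true_label,
                    status=row["status"],
                    offset=np.nan,
                    category="unknown-layout",
                    found_position=np.nan,
                    intended_position=np.nan,
                )
            )
            continue
        found_pos = fill[found_label]
        intended_pos = fill[true_label]
        offset = found_pos - intended_pos
        if plate_of[found_label] != plate_of[true_label]:
            cat = "cross-plate"
        elif abs(offset) == 1:
            cat = "off-by-one"
        elif abs(offset) == 2:
            cat = "off-by-two"
        else:
            cat = "long-range"
        records.append(
            dict(
                label=found_label,
                true_label=true_label,
                status=row["status"],
                offset=offset,
                category=cat,
                found_position=found_pos,
                intended_position=intended_pos,
            )
        )
    df = pd.DataFrame.from_records(
        records,
        columns=[
            "label",
            "true_label",
            "status",
            "offset",
            "category",
            "found_position",
            "intended_position",
        ],
    )
    if df.empty:
        df["run_id"] = pd.Series(dtype=int)
        df["run_length"] = pd.Series(dtype=int)
        return df
    df = df.sort_values("found_position", kind="stable").reset_index(drop=True)
    run_ids = np.zeros(len(df), dtype=int)
    rid = 0
    for i in range(1, len(df)):
        prev, cur = df.iloc[i - 1], df.iloc[i]
        contiguous = (
            np.isfinite(cur["found_position"])
            and np.isfinite(prev["found_position"])
            and cur["found_position"] == prev["found_position"] + 1
            and cur["offset"] == prev["offset"]
        )
        if not contiguous:
            rid += 1
        run_ids[i] = rid
    df["run_id"] = run_ids
    df["run_length"] = df.groupby("run_id")["run_id"].transform("size")
    return df


def plate_error_runs(classified: pd.DataFrame) -> pd.DataFrame:
    """Summary of maximal runs of consecutive equal offsets."""
    if classified.empty:
        return pd.DataFrame(columns=["run_id", "offset", "category", "length"])
    runs = (
        classified.groupby("run_id")
        .agg(
            offset=("offset", "first"),
            category=("category", "first"),
            length=("run_id", "size"),
        )
        .reset_index()
    )
    return runs
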