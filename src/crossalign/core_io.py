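"""Domain types shared across the package, plus readers/writers for the on-disk formats.

Genotypes are stored as small integer codes throughout: ``0 = BB`` (B6 homozygote),
``1 = BR`` (heterozygote), ``2 = RR`` (BTBR homozygote), ``-1 = NA``.  On the X
chromosome, hemizygous males are stored with the corresponding homozygous code,
since hemizygous and homozygous calls cannot be distinguished on a codominant
genotyping platform.

File dialects (all plain text):

* genotype CSV — samples in rows; first column sample id, second column sex,
  remaining columns one per marker (header row holds marker names);
* map CSV — columns ``marker, chromosome, position`` (cM); a chromosome named
  ``X`` (case-insensitive) is flagged as the X chromosome;
* expression matrix TSV/CSV — samples in rows, probes in columns; probe
  annotation CSV — columns ``probe, chromosome, position`` (cM);
* plate layout CSV — columns ``sample, plate, well`` with wells ``A01``–``H12``;
* diagnosis report — TSV plus a JSON mirror.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("crossalign")

# Canonical genotype codes (order matters: used as HMM state order).
GENO_LABELS = ("BB", "BR", "RR")
NA = -1
GENO_TO_CODE = {"BB": 0, "BR": 1, "RR": 2, "NA": NA}
CODE_TO_GENO = {0: "BB", 1: "BR", 2: "RR", NA: "NA"}

SEXES = ("female", "male", "unknown")

DIAGNOSIS_STATUSES = ("correct", "relabel", "duplicate", "unfixable", "unverifiable")

_WELL_RE = re.compile(r"^[A-H](0[1-9]|1[0-2])$")


class ValidationError(ValueError):
    """An input object violates one of its declared invariants."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class GeneticMap:
    """Marker names, chromosome assignments and cM positions for one cross."""

    markers: list[str]
    chromosomes: list[str]
    positions: np.ndarray  # cM, per marker
    x_chromosomes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if not (len(self.markers) == len(self.chromosomes) == len(self.positions)):
            raise ValidationError("map fields have mismatched lengths")
        _check_unique(self.markers, "marker names")
        if np.any(self.positions < 0) or np.any(~np.isfinite(self.positions)):
            raise ValidationError("marker positions must be finite and non-negative")
        for chrom in self.chromosome_names():
            pos = self.positions[self.chromosome_index(chrom)]
            if np.any(np.diff(pos) < 0):
                raise ValidationError(
                    f"marker positions not non-decreasing on chromosome {chrom}"
                )

    def chromosome_names(self) -> list[str]:
        """Chromosome names in first-appearance order."""
        return list(dict.fromkeys(self.chromosomes))

    def autosomes(self) -> list[str]:
        return [c for c in self.chromosome_names() if not self.is_x(c)]

    def is_x(self, chromosome: str) -> bool:
        return chromosome in self.x_chromosomes

    def chromosome_index(self, chromosome: str) -> np.ndarray:
        """Indices (into the marker list) of markers on a chromosome, map order."""
        idx = np.array(
            [i for i, c in enumerate(self.chromosomes) if c == chromosome], dtype=int
        )
        if idx.size == 0:
            raise KeyError(f"chromosome {chromosome!r} not in map")
        return idx

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class GenotypeTable:
    """Samples x markers categorical genotype calls with per-sample sex."""

    sample_ids: list[str]
    sex: list[str]
    calls: np.ndarray  # int8, samples x markers, codes {0,1,2,-1}
    markers: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        _check_unique(self.sample_ids, "sample ids")
        if len(self.sex) != len(self.sample_ids):
            raise ValidationError("sex vector length mismatch")
        bad_sex = set(self.sex) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sex values: {sorted(bad_sex)}")
        if self.calls.shape != (len(self.sample_ids), len(self.markers)):
            raise ValidationError("calls matrix shape mismatch")
        valid = np.isin(self.calls, (0, 1, 2, NA))
        if not valid.all():
            raise ValidationError("genotype codes outside {BB, BR, RR, NA}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def check_against_map(self, gmap: GeneticMap) -> None:
        if self.markers != gmap.markers:
            extra = sorted(set(self.markers) - set(gmap.markers))
            missing = sorted(set(gmap.markers) - set(self.markers))
            raise ValidationError(
                "genotype columns do not match the map: "
                f"not in map {extra}; missing from genotypes {missing}"
            )

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            list(self.sample_ids), list(self.sex), self.calls.copy(), list(self.markers)
        )


@dataclass
class ExpressionSet:
    """One tissue's samples x probes expression matrix with probe annotations.

    Values are on a log-ratio scale; ``NaN`` marks missing cells.  Probe
    locations may be unknown (chromosome ``None`` / position ``NaN``): such
    probes remain usable for between-tissue correlation work but are excluded
    from eQTL selection.
    """

    tissue: str
    sample_ids: list[str]
    values: np.ndarray  # float, samples x probes
    probe_ids: list[str]
    probe_chrom: list[str | None]
    probe_pos: np.ndarray  # cM, NaN = unknown

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_pos = np.asarray(self.probe_pos, dtype=float)
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.probe_ids, "probe ids")
        if self.values.shape != (len(self.sample_ids), len(self.probe_ids)):
            raise ValidationError("expression matrix shape mismatch")
        if not (len(self.probe_chrom) == len(self.probe_pos) == len(self.probe_ids)):
            raise ValidationError("probe annotation length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def probe_index(self, probe_ids: Iterable[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.probe_ids)}
        return np.array([lookup[p] for p in probe_ids], dtype=int)

    def copy(self) -> "ExpressionSet":
        return ExpressionSet(
            self.tissue,
            list(self.sample_ids),
            self.values.copy(),
            list(self.probe_ids),
            list(self.probe_chrom),
            self.probe_pos.copy(),
        )


@dataclass
class SimilarityMatrix:
    """Labeled rows x columns of similarity scores; NaN cells are missing."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    score_kind: str  # "correlation" | "match_proportion"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.row_ids, "row ids")
        _check_unique(self.col_ids, "column ids")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError("similarity matrix shape mismatch")
        if self.score_kind not in ("correlation", "match_proportion"):
            raise ValidationError(f"unknown score kind {self.score_kind!r}")
        finite = self.values[np.isfinite(self.values)]
        lo = -1.0 if self.score_kind == "correlation" else 0.0
        if finite.size and (finite.min() < lo - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValidationError(f"{self.score_kind} scores outside [{lo}, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


@dataclass
class Diagnosis:
    """Per-sample verdicts with their numeric evidence.

    One row per row-label of the similarity matrix that produced it, with the
    self similarity, the row maximum and its label, and the second-highest
    value — the quantities the relabeling rule is based on.
    """

    table: pd.DataFrame  # columns: label, status, inferred_label, self_score,
    #                      max_score, argmax_label, second_score

    COLUMNS = (
        "label",
        "status",
        "inferred_label",
        "self_score",
        "max_score",
        "argmax_label",
        "second_score",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"diagnosis table missing columns {sorted(missing)}")
        self.table = self.table.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        bad = set(self.table["status"]) - set(DIAGNOSIS_STATUSES)
        if bad:
            raise ValidationError(f"unknown statuses {sorted(bad)}")
        for _, row in self.table.iterrows():
            if row["status"] in ("relabel", "duplicate"):
                if not row["inferred_label"] or row["inferred_label"] == row["label"]:
                    raise ValidationError(
                        f"{row['status']} row {row['label']!r} needs a distinct inferred label"
                    )
            if row["status"] == "correct" and row["argmax_label"] != row["label"]:
                raise ValidationError(
                    f"correct row {row['label']!r} has argmax {row['argmax_label']!r}"
                )

    def rows_with_status(self, *statuses: str) -> pd.DataFrame:
        return self.table[self.table["status"].isin(statuses)]

    def relabel_map(self) -> dict[str, str]:
        """current label -> inferred true label, for relabel rows only."""
        rows = self.rows_with_status("relabel")
        return dict(zip(rows["label"], rows["inferred_label"]))

    def status_counts(self) -> dict[str, int]:
        counts = self.table["status"].value_counts().to_dict()
        return {s: int(counts.get(s, 0)) for s in DIAGNOSIS_STATUSES}


@dataclass
class PlateLayout:
    """Sample -> (plate, well) assignments for 96-well genotyping plates."""

    samples: list[str]
    plates: list[str]
    wells: list[str]

    def __post_init__(self) -> None:
        _check_unique(self.samples, "sample ids")
        if not (len(self.samples) == len(self.plates) == len(self.wells)):
            raise ValidationError("plate layout field length mismatch")
        for w in self.wells:
            if not _WELL_RE.match(w):
                raise ValidationError(f"malformed well {w!r} (expected e.g. 'A01')")
        pairs = list(zip(self.plates, self.wells))
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicate (plate, well) assignments")

    def fill_positions(self, order: str = "column-major") -> dict[str, int]:
        """Global filling-order index per sample.

        Plates are ordered by first appearance; within a plate, wells are
        ordered down columns (A01, B01, ..., H01, A02, ...) for
        ``column-major`` (the default, matching single-channel pipetting down
        a column) or along rows for ``row-major``.
        """
        if order not in ("column-major", "row-major"):
            raise ValueError(f"unknown fill order {order!r}")
        plate_order = {p: i for i, p in enumerate(dict.fromkeys(self.plates))}
        out: dict[str, int] = {}
        for s, p, w in zip(self.samples, self.plates, self.wells):
            row = ord(w[0]) - ord("A")
            col = int(w[1:]) - 1
            within = col * 8 + row if order == "column-major" else row * 12 + col
            out[s] = plate_order[p] * 96 + within
        return out

    def well_of(self, sample: str) -> tuple[str, str]:
        i = self.samples.index(sample)
        return self.plates[i], self.wells[i]


def well_name(within_plate_index: int, order: str = "column-major") -> str:
    """Inverse of the within-plate part of :meth:`PlateLayout.fill_positions`."""
    if not 0 <= within_plate_index < 96:
        raise ValueError("well index out of range")
    if order == "column-major":
        col, row = divmod(within_plate_index, 8)
    else:
        row, col = divmod(within_plate_index, 12)
    return f"{chr(ord('A') + row)}{col + 1:02d}"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

DEFAULT_CODE_MAP = {"BB": "BB", "BR": "BR", "RB": "BR", "RR": "RR", "NA": "NA", "": "NA", "-": "NA"}


def read_cross(
    genotype_file: str | Path,
    map_file: str | Path,
    code_map: Mapping[str, str] | None = None,
    x_chromosomes: Iterable[str] | None = None,
) -> tuple[GenotypeTable, GeneticMap]:
    """Read a genotype CSV and its genetic map CSV into validated objects.

    Unknown genotype codes are converted to NA with a logged count.  Markers
    present in the genotype file but absent from the map (or vice versa) are a
    hard error naming the offenders.
    """
    code_map = dict(DEFAULT_CODE_MAP if code_map is None else code_map)
    mdf = pd.read_csv(map_file, dtype={0: str, 1: str})
    mdf.columns = [c.strip().lower() for c in mdf.columns]
    if x_chromosomes is None:
        x_set = frozenset(c for c in mdf["chromosome"].unique() if str(c).upper() == "X")
    else:
        x_set = frozenset(x_chromosomes)
    gmap = GeneticMap(
        markers=mdf["marker"].astype(str).tolist(),
        chromosomes=mdf["chromosome"].astype(str).tolist(),
        positions=mdf["position"].to_numpy(float),
        x_chromosomes=x_set,
    )

    gdf = pd.read_csv(genotype_file, dtype=str, keep_default_na=False)
    sample_ids = gdf.iloc[:, 0].tolist()
    sex = [s.strip().lower() for s in gdf.iloc[:, 1]]
    sex = [s if s in SEXES else "unknown" for s in sex]
    markers = list(gdf.columns[2:])

    raw = gdf.iloc[:, 2:].to_numpy(dtype=object)
    calls = np.full(raw.shape, NA, dtype=np.int8)
    unknown = 0
    for code, canonical in code_map.items():
        calls[raw == code] = GENO_TO_CODE[canonical]
    recognized = np.isin(raw, list(code_map))
    unknown = int((~recognized).sum())
    if unknown:
        logger.warning("read_cross: %d unrecognized genotype codes set to NA", unknown)

    gt = GenotypeTable(sample_ids=sample_ids, sex=sex, calls=calls, markers=markers)
    gt.check_against_map(gmap)
    return gt, gmap


def write_cross(
    gt: GenotypeTable, gmap: GeneticMap, genotype_file: str | Path, map_file: str | Path
) -> None:
    mdf = pd.DataFrame(
        {"marker": gmap.markers, "chromosome": gmap.chromosomes, "position": gmap.positions}
    )
    mdf.to_csv(map_file, index=False)
    codes = np.array(["NA", "BB", "BR", "RR"], dtype=object)
    gdf = pd.DataFrame(codes[gt.calls + 1], columns=gt.markers)
    gdf.insert(0, "sex", gt.sex)
    gdf.insert(0, "id", gt.sample_ids)
    gdf.to_csv(genotype_file, index=False)


def read_expression(
    file: str | Path, annotation_file: str | Path, tissue: str
) -> ExpressionSet:
    """Read an expression matrix (samples x probes) and probe annotations.

    Probes without an annotation row get an unknown location; annotation rows
    for probes not in the matrix are ignored with a warning.
    """
    sep = "\t" if str(file).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(file, sep=sep, index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & df.notna() & (df.astype(str) != "")
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric expression value at sample {df.index[r]!r}, probe {df.columns[c]!r}"
        ) from None

    ann = pd.read_csv(annotation_file, dtype={0: str, 1: str})
    ann.columns = [c.strip().lower() for c in ann.columns]
    ann = ann.set_index("probe")
    extra = ann.index.difference(df.columns)
    if len(extra):
        logger.warning(
            "read_expression(%s): %d annotation rows for probes not in the matrix ignored",
            tissue,
            len(extra),
        )
    chrom: list[str | None] = []
    pos = np.full(df.shape[1], np.nan)
    n_unannotated = 0
    for j, p in enumerate(df.columns):
        if p in ann.index:
            c = ann.loc[p, "chromosome"]
            chrom.append(None if pd.isna(c) else str(c))
            pos[j] = ann.loc[p, "position"]
        else:
            chrom.append(None)
            n_unannotated += 1
    if n_unannotated:
        logger.info(
            "read_expression(%s): %d probes lack annotation (location unknown)",
            tissue,
            n_unannotated,
        )
    return ExpressionSet(
        tissue=tissue,
        sample_ids=df.index.astype(str).tolist(),
        values=values,
        probe_ids=df.columns.astype(str).tolist(),
        probe_chrom=chrom,
        probe_pos=pos,
    )


def write_expression(
    es: ExpressionSet, file: str | Path, annotation_file: str | Path | None = None
) -> None:
    sep = "\t" if str(file).endswith((".tsv", ".txt")) else ","
    df = pd.DataFrame(es.values, index=es.sample_ids, columns=es.probe_ids)
    df.index.name = "id"
    df.to_csv(file, sep=sep, float_format="%.17g")
    if annotation_file is not None:
        ann = pd.DataFrame(
            {"probe": es.probe_ids, "chromosome": es.probe_chrom, "position": es.probe_pos}
        )
        ann.to_csv(annotation_file, index=False)


def write_diagnosis(d: Diagnosis, path: str | Path) -> None:
    """Write a diagnosis report as TSV plus a machine-readable JSON mirror."""
    path = Path(path)
    d.table.to_csv(path, sep="\t", index=False)
    mirror = path.with_suffix(path.suffix + ".json")
    records = d.table.where(pd.notna(d.table), None).to_dict(orient="records")
    mirror.write_text(json.dumps({"diagnosis": records}, indent=1))


def read_diagnosis(path: str | Path) -> Diagnosis:
    """Re-read the JSON mirror written by :func:`write_diagnosis`."""
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(path.suffix + ".json")
    records = json.loads(path.read_text())["diagnosis"]
    df = pd.DataFrame(records, columns=list(Diagnosis.COLUMNS))
    for col in ("self_score", "max_score", "second_score"):
        df[col] = pd.to_numeric(df[col])
    return Diagnosis(df)


def read_plate_layout(path: str | Path) -> PlateLayout:
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    return PlateLayout(
        samples=df["sample"].tolist(), plates=df["plate"].tolist(), wells=df["well"].tolist()
    )


def write_plate_layout(layout: PlateLayout, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": layout.samples, "plate": layout.plates, "well": layout.wells}
    ).to_csv(path, index=False)
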