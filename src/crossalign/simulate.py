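"""Synthetic multi-tissue F2 eQTL studies with planted, ledgered sample mix-ups.

The generator emulates the structure of a BTBR x B6 F2 intercross expression
study: F2 genotypes from two recombinant gametes per autosome (first-order
Markov chains over markers, with per-interval recombination fractions from the
configured map function), an X chromosome following the cross design (females
RR or BR; hemizygous males stored as the homozygous code), symmetric
genotyping errors and missing calls, and per-tissue expression matrices with

* a block of tissue-shared probes driven by per-mouse latent factors (so the
  between-tissue probe correlations used for array alignment exist),
* per-tissue large-effect local eQTL probes (additive + dominance effects
  sized so the single-position LOD far exceeds 100 at the default n),
* an Xist-like (female-high) and a Y-like (male-high) sex probe, and
* pure-noise probes for the remainder.

Samples are plated in same-sex blocks of 24 filling-order wells, as in real
plating practice, so plate-shift errors do not trivially reveal themselves
through sex checks.

``plant_errors`` then corrupts the clean study with a configurable list of
errors — DNA swaps, DNA duplicates, plate-shift runs, within-tissue expression
swaps / k-cycles / duplicates, and recorded-sex swaps — while a
:class:`TruthLedger` records every displacement in canonical form, so the
corruption is exactly invertible and every detector can be scored against
ground truth.

A plate shift of ``length`` at offset +1 is implemented as a cyclic rotation
of the DNA across ``length + 1`` consecutive filling-order wells: each of the
first ``length`` displaced samples lands one well below its intended position
(a run of consecutive off-by-one errors) and the last displaced sample wraps
back to the vacated first well (one long-range error).  This keeps the planted
corruption a pure permutation, so the ledger inverse is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core_io import (
    NA,
    ExpressionSet,
    GeneticMap,
    GenotypeTable,
    PlateLayout,
    well_name,
    write_cross,
    write_expression,
    write_plate_layout,
)
from .genmap import inverse_map_r


@dataclass
class SimConfig:
    """Parameters of one synthetic study.  Defaults are the package's standard
    test scenario: 300 mice, 5 autosomes + X, 3 tissues x 1000 probes."""

    n_mice: int = 300
    autosome_lengths_cM: tuple[float, ...] = (100.0, 90.0, 80.0, 65.0, 50.0)
    markers_per_autosome: int = 20
    x_length_cM: float = 60.0
    x_markers: int = 10
    map_function: str = "carter_falconer"
    error_rate: float = 0.002
    missing_rate: float = 0.01
    sex_block_size: int = 24  # same-sex plating blocks, in filling order
    tissues: tuple[str, ...] = ("adipose", "gastroc", "islet")
    n_probes: int = 1000
    n_shared_probes: int = 120
    shared_loading: float = 3.0  # between-tissue probe correlation = l^2/(l^2+1)
    n_eqtl_per_tissue: int = 60
    n_paired_eqtl: int = 2  # eQTL units carrying two probes
    eqtl_additive: float = 4.0
    eqtl_dominance: float = 0.5
    eqtl_sd: float = 1.0
    sex_effect: float = 2.0
    n_no_expression: int = 6  # mice genotyped but never assayed for expression
    planted_errors: list[dict] | None = None  # None -> default_planted_errors()
    seed: int = 0

    def validate(self) -> None:
        if self.n_mice <= 0 or self.n_probes <= 0 or self.markers_per_autosome < 2:
            raise ValueError("counts must be positive (>=2 markers per autosome)")
        if not 0 <= self.error_rate < 0.5 or not 0 <= self.missing_rate < 1:
            raise ValueError("error/missing rates out of range")
        needed = self.n_shared_probes + 2 + self.n_eqtl_per_tissue + self.n_paired_eqtl
        if needed > self.n_probes:
            raise ValueError("n_probes too small for the configured probe blocks")
        if self.n_no_expression >= self.n_mice:
            raise ValueError("n_no_expression must leave assayed mice")


def default_planted_errors() -> list[dict]:
    """The standard planted-error scenario: 10 wrong DNA rows (a plate-shift
    rotation giving a run of 8 off-by-one errors plus its wrap-back, and one
    standalone DNA duplicate), one expression swap per tissue, a 3-cycle in
    the first tissue, an expression duplicate in the last tissue, and one
    recorded-sex swap (2 sex-discordant samples)."""
    return [
        {"kind": "dna_plate_shift", "start_fill": 2, "length": 8, "offset": 1},
        {"kind": "dna_duplicate", "source_fill": 40, "target_fill": 41},
        {"kind": "expr_swap", "tissue_index": 0, "fills": [60, 61]},
        {"kind": "expr_swap", "tissue_index": 1, "fills": [62, 63]},
        {"kind": "expr_swap", "tissue_index": 2, "fills": [64, 65]},
        {"kind": "expr_cycle", "tissue_index": 0, "fills": [70, 71, 72]},
        {"kind": "expr_duplicate", "tissue_index": 2, "source_fill": 80, "target_fill": 81},
        {"kind": "sex_swap", "search_from_fill": 100},
    ]


@dataclass
class TruthLedger:
    """Ground truth for one corrupted study.

    ``dna_source[label]`` / ``expr_source[tissue][label]`` give the true
    sample whose data sits in the row bearing ``label`` (identity omitted);
    ``dna_overwritten`` keeps rows destroyed by duplication so the corruption
    is exactly invertible.
    """

    planted: list[dict] = field(default_factory=list)
    dna_source: dict[str, str] = field(default_factory=dict)
    dna_overwritten: dict[str, np.ndarray] = field(default_factory=dict)
    expr_source: dict[str, dict[str, str]] = field(default_factory=dict)
    expr_overwritten: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    sex_swapped: list[str] = field(default_factory=list)
    true_sex: dict[str, str] = field(default_factory=dict)
    true_crossovers: dict[str, int] = field(default_factory=dict)
    eqtl_truth: list[dict] = field(default_factory=list)

    def expected_dna_relabels(self) -> dict[str, str]:
        """label -> true sample, for rows holding someone else's DNA (excluding
        duplicate rows, whose true sample already has a correct row)."""
        dup_targets = set(self.dna_overwritten)
        return {
            l: s for l, s in self.dna_source.items() if l != s and l not in dup_targets
        }

    def expected_dna_duplicates(self) -> dict[str, str]:
        return {l: self.dna_source[l] for l in self.dna_overwritten}

    def expected_expr_relabels(self, tissue: str) -> dict[str, str]:
        dup_targets = set(self.expr_overwritten.get(tissue, {}))
        return {
            l: s
            for l, s in self.expr_source.get(tissue, {}).items()
            if l != s and l not in dup_targets
        }

    def expected_expr_duplicates(self, tissue: str) -> dict[str, str]:
        src = self.expr_source.get(tissue, {})
        return {l: src[l] for l in self.expr_overwritten.get(tissue, {})}

    def restore_genotypes(self, gt: GenotypeTable) -> GenotypeTable:
        """Invert the planted DNA corruption (permutation + stored originals)."""
        idx = {s: i for i, s in enumerate(gt.sample_ids)}
        calls = gt.calls.copy()
        # undo the permutation: the clean row of sample s is wherever s's DNA sits
        holder_of = {src: label for label, src in self.dna_source.items()}
        for sample, holder in holder_of.items():
            calls[idx[sample]] = gt.calls[idx[holder]]
        for label, original in self.dna_overwritten.items():
            calls[idx[label]] = original
        sex = list(gt.sex)
        for s in self.sex_swapped:
            sex[idx[s]] = self.true_sex[s]
        return GenotypeTable(list(gt.sample_ids), sex, calls, list(gt.markers))

    def restore_expression(self, es: ExpressionSet) -> ExpressionSet:
        idx = {s: i for i, s in enumerate(es.sample_ids)}
        values = es.values.copy()
        src = self.expr_source.get(es.tissue, {})
        holder_of = {s: label for label, s in src.items()}
        for sample, holder in holder_of.items():
            values[idx[sample]] = es.values[idx[holder]]
        for label, original in self.expr_overwritten.get(es.tissue, {}).items():
            values[idx[label]] = original
        out = es.copy()
        out.values = values
        return out

    def to_json(self) -> str:
        payload = {
            "planted": self.planted,
            "dna_source": self.dna_source,
            "dna_overwritten": {k: v.tolist() for k, v in self.dna_overwritten.items()},
            "expr_source": self.expr_source,
            "expr_overwritten": {
                t: {k: v.tolist() for k, v in d.items()}
                for t, d in self.expr_overwritten.items()
            },
            "sex_swapped": self.sex_swapped,
            "true_sex": self.true_sex,
            "true_crossovers": self.true_crossovers,
            "eqtl_truth": self.eqtl_truth,
        }
        return json.dumps(payload, indent=1)


def _simulate_gamete(rng: np.random.Generator, n_mice: int, rs: np.ndarray) -> np.ndarray:
    """Recombinant gametes as Markov chains: (n_mice x n_markers) alleles 0/1."""
    n_markers = len(rs) + 1
    g = np.empty((n_mice, n_markers), dtype=np.int8)
    g[:, 0] = rng.random(n_mice) < 0.5
    for k, r in enumerate(rs):
        flip = rng.random(n_mice) < r
        g[:, k + 1] = np.where(flip, 1 - g[:, k], g[:, k])
    return g


def simulate_cross(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeTable, GeneticMap, PlateLayout, TruthLedger]:
    """Simulate genotypes, map and plate layout for one F2 panel.

    Returns the clean (pre-planting) genotype table with genotyping errors and
    missing calls already applied, and a ledger seeded with true sexes and
    true (pre-error) crossover counts.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_mice
    sample_ids = [f"Mouse{3001 + i}" for i in range(n)]

    # same-sex plating blocks in filling order (= id order)
    sex = [
        "female" if (i // cfg.sex_block_size) % 2 == 0 else "male" for i in range(n)
    ]

    markers: list[str] = []
    chroms: list[str] = []
    positions: list[float] = []
    for c, length in enumerate(cfg.autosome_lengths_cM, start=1):
        pos = np.linspace(0, length, cfg.markers_per_autosome)
        for j, p in enumerate(pos):
            markers.append(f"c{c}m{j + 1}")
            chroms.append(str(c))
            positions.append(float(p))
    xpos = np.linspace(0, cfg.x_length_cM, cfg.x_markers)
    for j, p in enumerate(xpos):
        markers.append(f"cXm{j + 1}")
        chroms.append("X")
        positions.append(float(p))
    gmap = GeneticMap(markers, chroms, np.array(positions), x_chromosomes=frozenset({"X"}))

    true_calls = np.empty((n, len(markers)), dtype=np.int8)
    col = 0
    xovers = np.zeros(n, dtype=int)
    for length in cfg.autosome_lengths_cM:
        pos = np.linspace(0, length, cfg.markers_per_autosome)
        rs = np.array(
            [inverse_map_r(float(d), cfg.map_function) for d in np.diff(pos)]
        )
        g1 = _simulate_gamete(rng, n, rs)
        g2 = _simulate_gamete(rng, n, rs)
        geno = (g1 + g2).astype(np.int8)  # 0=BB, 1=BR, 2=RR
        true_calls[:, col : col + cfg.markers_per_autosome] = geno
        xovers += (np.diff(geno, axis=1) != 0).sum(axis=1)
        col += cfg.markers_per_autosome

    # X: paternal allele is R (from the F1 male, whose X is pure BTBR);
    # maternal gamete recombines.  Hemizygous males stored as homozygous.
    rsx = np.array(
        [inverse_map_r(float(d), cfg.map_function) for d in np.diff(xpos)]
    )
    maternal = _simulate_gamete(rng, n, rsx)  # 0=B allele, 1=R allele
    is_female = np.array([s == "female" for s in sex])
    xgeno = np.where(
        is_female[:, None],
        1 + maternal,  # R + {B,R} -> BR (1) or RR (2)
        2 * maternal,  # hemizygous: B -> coded BB (0), R -> coded RR (2)
    ).astype(np.int8)
    true_calls[:, col:] = xgeno

    # genotyping errors: symmetric among the two wrong codes
    calls = true_calls.copy()
    err = rng.random(calls.shape) < cfg.error_rate
    shift = rng.integers(1, 3, size=calls.shape, dtype=np.int8)
    calls[err] = (calls[err] + shift[err]) % 3
    calls[rng.random(calls.shape) < cfg.missing_rate] = NA

    plates = [f"plate{1 + i // 96}" for i in range(n)]
    wells = [well_name(i % 96) for i in range(n)]
    layout = PlateLayout(samples=list(sample_ids), plates=plates, wells=wells)

    ledger = TruthLedger(
        true_sex=dict(zip(sample_ids, sex)),
        true_crossovers={s: int(x) for s, x in zip(sample_ids, xovers)},
    )
    gt = GenotypeTable(sample_ids, sex, calls, markers)
    gt._true_calls = true_calls  # pre-error calls, used by simulate_expression
    return gt, gmap, layout, ledger


def simulate_expression(
    cfg: SimConfig,
    gt: GenotypeTable,
    gmap: GeneticMap,
    ledger: TruthLedger,
    rng: np.random.Generator | None = None,
) -> dict[str, ExpressionSet]:
    """Per-tissue expression sets for the assayed mice.

    Probe blocks (indices): tissue-shared latent-factor probes, then the
    Xist-like and Y-like sex probes, then per-tissue local-eQTL probes
    (disjoint ranges across tissues, annotated at their marker's position),
    then pure noise.  Expression depends on the *true* genotypes, so a planted
    DNA error later shows up as a genotype/expression mismatch.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_mice
    true_calls = getattr(gt, "_true_calls", gt.calls)
    assayed = list(range(n - cfg.n_no_expression))
    sample_ids = [gt.sample_ids[i] for i in assayed]
    is_female = np.array([gt.sex[i] == "female" for i in assayed])

    probe_ids = [f"p{j + 1:04d}" for j in range(cfg.n_probes)]
    shared_idx = list(range(cfg.n_shared_probes))
    xist_idx = cfg.n_shared_probes
    ychr_idx = cfg.n_shared_probes + 1
    eqtl_start = cfg.n_shared_probes + 2

    # per-mouse latent factors shared across tissues
    factors = rng.standard_normal((len(assayed), cfg.n_shared_probes))

    # autosomal markers usable as eQTL locations
    auto_markers = [
        (j, gmap.chromosomes[j], float(gmap.positions[j]))
        for j in range(gmap.n_markers)
        if not gmap.is_x(gmap.chromosomes[j])
    ]

    sets: dict[str, ExpressionSet] = {}
    for t_i, tissue in enumerate(cfg.tissues):
        values = rng.standard_normal((len(assayed), cfg.n_probes))
        chrom_ann: list[str | None] = [None] * cfg.n_probes
        pos_ann = np.full(cfg.n_probes, np.nan)

        for f, j in enumerate(shared_idx):
            values[:, j] = cfg.shared_loading * factors[:, f] + rng.standard_normal(
                len(assayed)
            )
        values[:, xist_idx] = cfg.sex_effect * is_female + 0.5 * rng.standard_normal(
            len(assayed)
        )
        chrom_ann[xist_idx] = "X"
        pos_ann[xist_idx] = cfg.x_length_cM / 2
        values[:, ychr_idx] = cfg.sex_effect * (~is_female) + 0.5 * rng.standard_normal(
            len(assayed)
        )
        chrom_ann[ychr_idx] = "Y"

        # per-tissue eQTL block: n_eqtl distinct marker locations; the first
        # n_paired locations carry two probes each
        n_units = cfg.n_eqtl_per_tissue
        n_probes_eqtl = n_units + cfg.n_paired_eqtl
        loc_choice = rng.choice(len(auto_markers), size=n_units, replace=False)
        start = eqtl_start + t_i * (cfg.n_eqtl_per_tissue + cfg.n_paired_eqtl)
        probe_j = start
        for u, li in enumerate(loc_choice):
            mcol, chrom, pos = auto_markers[li]
            g = true_calls[np.ix_(assayed, [mcol])][:, 0].astype(float)
            n_probes_here = 2 if u < cfg.n_paired_eqtl else 1
            for _ in range(n_probes_here):
                signal = cfg.eqtl_additive * (g - 1) + cfg.eqtl_dominance * (g == 1)
                values[:, probe_j] = signal + cfg.eqtl_sd * rng.standard_normal(
                    len(assayed)
                )
                chrom_ann[probe_j] = chrom
                pos_ann[probe_j] = pos
                ledger.eqtl_truth.append(
                    dict(
                        tissue=tissue,
                        probe=probe_ids[probe_j],
                        chromosome=chrom,
                        position_cM=pos,
                        additive=cfg.eqtl_additive,
                        dominance=cfg.eqtl_dominance,
                        sd=cfg.eqtl_sd,
                    )
                )
                probe_j += 1
        assert probe_j == start + n_probes_eqtl

        sets[tissue] = ExpressionSet(
            tissue=tissue,
            sample_ids=list(sample_ids),
            values=values,
            probe_ids=list(probe_ids),
            probe_chrom=chrom_ann,
            probe_pos=pos_ann,
        )
    return sets


def _fill_to_sample(layout: PlateLayout, order: str = "column-major") -> dict[int, str]:
    return {f: s for s, f in layout.fill_positions(order).items()}


def plant_errors(
    cfg: SimConfig,
    gt: GenotypeTable,
    expr_sets: dict[str, ExpressionSet],
    layout: PlateLayout,
    ledger: TruthLedger,
) -> tuple[GenotypeTable, dict[str, ExpressionSet], TruthLedger]:
    """Apply the configured planted errors; record everything in the ledger.

    Raises at validation time if two errors touch the same sample slot.
    """
    errors = cfg.planted_errors if cfg.planted_errors is not None else default_planted_errors()
    fill_sample = _fill_to_sample(layout)
    idx = {s: i for i, s in enumerate(gt.sample_ids)}
    tissues = list(expr_sets)

    dna_touched: set[str] = set()
    expr_touched: dict[str, set[str]] = {t: set() for t in tissues}

    def claim_dna(*samples: str) -> None:
        for s in samples:
            if s in dna_touched:
                raise ValueError(f"planted errors touch DNA sample {s} twice")
            dna_touched.add(s)

    def claim_expr(tissue: str, *samples: str) -> None:
        for s in samples:
            if s in expr_touched[tissue]:
                raise ValueError(f"planted errors touch {tissue} array {s} twice")
            expr_touched[tissue].add(s)

    # DNA corruption built as a permutation (dna_src) plus overwrites
    dna_src = {s: s for s in gt.sample_ids}
    new_gt = gt.copy()
    new_sets = {t: es.copy() for t, es in expr_sets.items()}

    for err in errors:
        kind = err["kind"]
        if kind == "dna_plate_shift":
            start, length = int(err["start_fill"]), int(err["length"])
            offset = int(err.get("offset", 1))
            if abs(offset) != 1:
                raise ValueError("plate shifts are modeled at |offset| = 1")
            run = [fill_sample[start + i] for i in range(length + 1)]
            claim_dna(*run)
            # sample intended at well i lands at well i+1; the last wraps back
            for i in range(1, length + 1):
                dna_src[run[i]] = run[i - 1]
            dna_src[run[0]] = run[-1]
            ledger.planted.append(
                dict(
                    kind=kind,
                    start_fill=start,
                    length=length,
                    offset=offset,
                    samples=run,
                )
            )
        elif kind == "dna_swap":
            a = err.get("sample_a") or fill_sample[int(err["fill_a"])]
            b = err.get("sample_b") or fill_sample[int(err["fill_b"])]
            claim_dna(a, b)
            dna_src[a], dna_src[b] = b, a
            ledger.planted.append(dict(kind=kind, samples=[a, b]))
        elif kind == "dna_duplicate":
            src = err.get("source") or fill_sample[int(err["source_fill"])]
            dst = err.get("target") or fill_sample[int(err["target_fill"])]
            claim_dna(src, dst)
            ledger.dna_overwritten[dst] = gt.calls[idx[dst]].copy()
            new_gt.calls[idx[dst]] = gt.calls[idx[src]]
            dna_src[dst] = src
            ledger.planted.append(dict(kind=kind, samples=[src, dst]))
        elif kind in ("expr_swap", "expr_cycle", "expr_duplicate"):
            tissue = err.get("tissue") or tissues[int(err["tissue_index"])]
            es, new_es = expr_sets[tissue], new_sets[tissue]
            eidx = {s: i for i, s in enumerate(es.sample_ids)}
            if kind == "expr_duplicate":
                src = err.get("source") or fill_sample[int(err["source_fill"])]
                dst = err.get("target") or fill_sample[int(err["target_fill"])]
                claim_expr(tissue, dst)
                ledger.expr_overwritten.setdefault(tissue, {})[dst] = es.values[
                    eidx[dst]
                ].copy()
                new_es.values[eidx[dst]] = es.values[eidx[src]]
                ledger.expr_source.setdefault(tissue, {})[dst] = src
                ledger.planted.append(dict(kind=kind, tissue=tissue, samples=[src, dst]))
            else:
                cyc = err.get("samples") or [fill_sample[int(f)] for f in err["fills"]]
                if kind == "expr_swap" and len(cyc) != 2:
                    raise ValueError("expr_swap takes exactly two samples")
                claim_expr(tissue, *cyc)
                # row labeled cyc[i] holds the array of cyc[i+1]
                for i, label in enumerate(cyc):
                    src = cyc[(i + 1) % len(cyc)]
                    new_es.values[eidx[label]] = es.values[eidx[src]]
                    ledger.expr_source.setdefault(tissue, {})[label] = src
                ledger.planted.append(dict(kind=kind, tissue=tissue, samples=cyc))
        elif kind == "sex_swap":
            if "sample_a" in err:
                a, b = err["sample_a"], err["sample_b"]
            else:
                a, b = _find_sex_swap_pair(
                    gt, int(err.get("search_from_fill", 0)), fill_sample, dna_touched
                )
            if gt.sex[idx[a]] == gt.sex[idx[b]]:
                raise ValueError("sex_swap needs a male/female pair")
            new_gt.sex[idx[a]], new_gt.sex[idx[b]] = (
                gt.sex[idx[b]],
                gt.sex[idx[a]],
            )
            ledger.sex_swapped.extend([a, b])
            ledger.planted.append(dict(kind=kind, samples=[a, b]))
        else:
            raise ValueError(f"unknown planted error kind {kind!r}")

    # apply the DNA permutation (duplicates already written)
    src_rows = np.array([idx[dna_src[s]] for s in gt.sample_ids])
    perm_calls = gt.calls[src_rows]
    for dst in ledger.dna_overwritten:  # duplicate rows keep their copied DNA
        perm_calls[idx[dst]] = new_gt.calls[idx[dst]]
    new_gt.calls = perm_calls
    ledger.dna_source.update({s: d for s, d in dna_src.items() if s != d})
    return new_gt, new_sets, ledger


def _find_sex_swap_pair(
    gt: GenotypeTable,
    start_fill: int,
    fill_sample: dict[int, str],
    exclude: set[str],
    min_discordant: int = 2,
) -> tuple[str, str]:
    """First male/female pair (scanning filling order) whose X genotypes make a
    recorded-sex swap detectable: the male shows >= min_discordant hemizygous-B
    (coded BB) X calls, the female >= min_discordant heterozygous X calls."""
    idx = {s: i for i, s in enumerate(gt.sample_ids)}
    x_cols = [j for j, m in enumerate(gt.markers) if m.startswith("cXm")]
    male = female = None
    for f in range(start_fill, max(fill_sample) + 1):
        s = fill_sample.get(f)
        if s is None or s in exclude:
            continue
        xrow = gt.calls[idx[s], x_cols]
        if gt.sex[idx[s]] == "male" and male is None:
            if int((xrow == 0).sum()) >= min_discordant:
                male = s
        elif gt.sex[idx[s]] == "female" and female is None:
            if int((xrow == 1).sum()) >= min_discordant:
                female = s
        if male and female:
            return male, female
    raise RuntimeError("no detectable sex-swap pair found; enlarge the panel")


@dataclass
class SimulatedStudy:
    """A complete corrupted study plus its ground truth."""

    config: SimConfig
    genotypes: GenotypeTable
    genetic_map: GeneticMap
    layout: PlateLayout
    expression: dict[str, ExpressionSet]
    ledger: TruthLedger
    clean_genotypes: GenotypeTable = field(repr=False, default=None)
    clean_expression: dict[str, ExpressionSet] = field(repr=False, default=None)


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Full generator: cross -> expression -> planted errors.

    All randomness flows from ``cfg.seed`` through spawned child generators
    (one per stage), so every sub-result is reproducible in isolation.
    """
    cfg.validate()
    rng_cross, rng_expr = np.random.default_rng(cfg.seed).spawn(2)
    gt_clean, gmap, layout, ledger = simulate_cross(cfg, rng_cross)
    expr_clean = simulate_expression(cfg, gt_clean, gmap, ledger, rng_expr)
    gt, expr, ledger = plant_errors(cfg, gt_clean, expr_clean, layout, ledger)
    return SimulatedStudy(
        config=cfg,
        genotypes=gt,
        genetic_map=gmap,
        layout=layout,
        expression=expr,
        ledger=ledger,
        clean_genotypes=gt_clean,
        clean_expression=expr_clean,
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write the corrupted study to disk in the package's text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cross(study.genotypes, study.genetic_map, outdir / "genotypes.csv", outdir / "map.csv")
    write_plate_layout(study.layout, outdir / "plates.csv")
    for tissue, es in study.expression.items():
        write_expression(es, outdir / f"expression_{tissue}.tsv", outdir / f"annotation_{tissue}.csv")
    (outdir / "truth_ledger.json").write_text(study.ledger.to_json())
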