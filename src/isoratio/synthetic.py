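"""Synthetic two-cohort isoform data with known ground truth.

The generator emulates the statistical structure of a bulk RNA-seq tumor
cohort quantified at isoform level (TPM), so that every downstream stage —
QC filtering, DIR testing, per-sample clustering, junction validation,
enrichment — can be exercised against planted effects:

* two unbalanced sample groups (primary / metastatic);
* per-gene isoform proportion vectors with group-specific **switches**
  (``dir_delta`` proportion mass moved between two isoforms in the
  metastatic group);
* gene-level differential expression on a subset of genes;
* tumor/contaminant **impurity** mixtures, with a correlated immune
  program shared by the designated infiltrate samples;
* **3'-fragment bias** that shifts mass onto a designated fragment isoform
  while conserving the gene total exactly;
* multiplicative per-gene batch factors;
* split-read junction counts Poisson-consistent with the true per-sample
  inclusion proportions.

Distributional choices (Dirichlet proportions around group centers,
log-normal gene totals, Beta purity/bias scores, a detection floor that
zeroes very low abundances) are the package's own: they reproduce the
qualitative features the downstream methods must survive, not any specific
dataset.  See docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .io import IsoformCountMatrix
from .junctions import JunctionCountTable, JunctionEvent


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a scaled-down melanoma-like cohort: unbalanced
    groups, ~10% of genes with an isoform switch of 0.3 proportion mass,
    moderate impurity (purity ~ Beta(8,2), mean 0.8) and mild 3' bias
    (Beta(2,6), mean 0.25, mostly below the 0.55 QC cutoff).
    """

    n_primary: int = 50
    n_metastatic: int = 150
    n_genes: int = 200
    isoforms_per_gene_range: tuple[int, int] = (1, 5)
    frac_dir_genes: float = 0.1
    dir_delta: float = 0.3
    frac_de_genes: float = 0.2
    de_log2fc_range: tuple[float, float] = (0.5, 2.0)
    dirichlet_concentration: float = 25.0
    frac_infiltrate_samples: float = 0.2
    #: Beta(a, b) purity per group (primary, metastatic); b = 0 means
    #: purity exactly 1
    purity_beta_params: tuple[tuple[float, float], tuple[float, float]] = (
        (8.0, 2.0), (8.0, 2.0))
    bias_beta_params: tuple[tuple[float, float], tuple[float, float]] = (
        (2.0, 6.0), (2.0, 6.0))
    bias_strength: float = 0.5
    n_batches: int = 3
    batch_sd: float = 0.1
    junction_depth: float = 200.0
    detection_floor: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_primary, self.n_metastatic, self.n_genes,
               self.n_batches) < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.isoforms_per_gene_range
        if not (1 <= lo <= hi):
            raise ValueError("isoforms_per_gene_range must satisfy 1 <= min <= max")
        for name in ("frac_dir_genes", "frac_de_genes",
                     "frac_infiltrate_samples", "bias_strength"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.dir_delta < 1:
            raise ValueError("dir_delta must lie in (0, 1)")
        if not 0 < self.de_log2fc_range[0] <= self.de_log2fc_range[1]:
            raise ValueError("de_log2fc_range must be a positive pair")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        for pair in (*self.purity_beta_params, *self.bias_beta_params):
            if pair[0] <= 0 or pair[1] < 0:
                raise ValueError("beta parameters must be positive (b = 0 "
                                 "allowed as a point mass at 1)")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be non-negative")
        if self.junction_depth <= 0:
            raise ValueError("junction_depth must be positive")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("isoforms_per_gene_range", "de_log2fc_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("purity_beta_params", "bias_beta_params"):
            if key in raw:
                raw[key] = tuple(tuple(p) for p in raw[key])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Every effect the generator planted.

    ``dir_genes`` maps gene id -> (source isoform, destination isoform,
    delta moved); ``event_psi`` holds the true per-sample inclusion
    proportion of each event gene's source isoform, before impurity/bias
    distortion.
    """

    dir_genes: dict[str, tuple[str, str, float]] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)
    immune_genes: set[str] = field(default_factory=set)
    infiltrate_samples: set[str] = field(default_factory=set)
    fragment_isoforms: dict[str, str] = field(default_factory=dict)
    event_map: dict[str, JunctionEvent] = field(default_factory=dict)
    event_psi: Optional[pd.DataFrame] = None

    def to_json(self, path) -> None:
        payload = {
            "dir_genes": {g: list(v) for g, v in self.dir_genes.items()},
            "de_genes": self.de_genes,
            "immune_genes": sorted(self.immune_genes),
            "infiltrate_samples": sorted(self.infiltrate_samples),
            "fragment_isoforms": self.fragment_isoforms,
            "event_map": {
                g: {"event_type": ev.event_type,
                    "favored_direction": ev.favored_direction,
                    "junctions": {r: list(j) for r, j in ev.junctions.items()}}
                for g, ev in self.event_map.items()
            },
            "event_psi": (None if self.event_psi is None
                          else self.event_psi.to_dict(orient="split")),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        psi = raw.get("event_psi")
        return cls(
            dir_genes={g: tuple(v) for g, v in raw["dir_genes"].items()},
            de_genes=raw["de_genes"],
            immune_genes=set(raw["immune_genes"]),
            infiltrate_samples=set(raw["infiltrate_samples"]),
            fragment_isoforms=raw["fragment_isoforms"],
            event_map={
                g: JunctionEvent(
                    g, d["event_type"],
                    {r: tuple(j) for r, j in d["junctions"].items()},
                    d["favored_direction"])
                for g, d in raw["event_map"].items()
            },
            event_psi=(None if psi is None else pd.DataFrame(
                psi["data"], index=psi["index"], columns=psi["columns"])),
        )


# ---------------------------------------------------------------------------
# elementary distortions
# ---------------------------------------------------------------------------

def apply_impurity(
    tumor_profile: pd.Series,
    contaminant_profile: pd.Series,
    purity: float,
) -> pd.Series:
    """Linear mixture purity*tumor + (1-purity)*contaminant."""
    if not 0 <= purity <= 1:
        raise ValueError("purity must lie in [0, 1]")
    if not tumor_profile.index.equals(contaminant_profile.index):
        raise ValueError("profiles must share the same isoform index")
    return purity * tumor_profile + (1.0 - purity) * contaminant_profile


def bias_transfer_fraction(bias_score: float, bias_strength: float) -> float:
    """Fraction of non-fragment mass moved to the fragment isoform.

    Piecewise linear: zero up to bias score 0.4, then rising so the QC
    cutoff (0.55) sits inside the active range:
    f = strength * max(0, (score - 0.4) / 0.6).
    """
    return bias_strength * max(0.0, (bias_score - 0.4) / 0.6)


def apply_fragment_bias(
    gene_counts: pd.Series,
    fragment_isoform: Optional[str],
    bias_score: float,
    bias_strength: float,
) -> pd.Series:
    """Skew one gene's isoform vector toward its 3'-fragment isoform.

    A fraction ``f = bias_strength * max(0, (bias_score - 0.4)/0.6)`` of
    the total non-fragment mass moves onto the fragment isoform; the gene
    total is conserved exactly.  Genes without a fragment isoform are
    returned unchanged.
    """
    if fragment_isoform is None or fragment_isoform not in gene_counts.index:
        return gene_counts.copy()
    f = bias_transfer_fraction(bias_score, bias_strength)
    if f <= 0:
        return gene_counts.copy()
    out = gene_counts.astype(float).copy()
    others = out.index != fragment_isoform
    moved = f * out[others].sum()
    out[others] *= (1.0 - f)
    out[fragment_isoform] += moved
    return out


def _beta_draw(rng: np.random.Generator, pair, size: int) -> np.ndarray:
    a, b = pair
    if b == 0:  # convention: point mass at 1 (e.g. perfectly pure samples)
        return np.ones(size)
    return rng.beta(a, b, size)


# ---------------------------------------------------------------------------
# the cohort generator
# ---------------------------------------------------------------------------

#: fraction of genes carrying the contaminant immune program, and its
#: fold-up in the contaminant profile
_IMMUNE_GENE_FRAC = 0.05
_IMMUNE_FOLD = 8.0
#: log-normal parameters of gene base abundance (TPM) and per-sample noise
_GENE_MEANLOG = 3.0
_GENE_SDLOG = 1.0
_SAMPLE_SDLOG = 0.3
#: symmetric Dirichlet concentration of baseline isoform proportions
_BASELINE_ALPHA = 2.0
#: margin kept on the switch source isoform so the full delta is movable
_DIR_MARGIN = 0.05


def generate_cohort(
    config: CohortConfig,
) -> tuple[IsoformCountMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate one cohort: counts matrix, metadata, and planted truth.

    Deterministic given the config (identical config + seed reproduce the
    outputs bit for bit).  Raises when isoform switches are requested but
    no gene has >= 2 isoforms.
    """
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(config.seed).spawn(5)]
    r_struct, r_props, r_totals, r_qc, _ = rngs

    n_samples = config.n_primary + config.n_metastatic
    sample_ids = ([f"PT{i + 1:03d}" for i in range(config.n_primary)]
                  + [f"MET{i + 1:03d}" for i in range(config.n_metastatic)])
    is_met = np.array([False] * config.n_primary
                      + [True] * config.n_metastatic)

    lo, hi = config.isoforms_per_gene_range
    n_iso = r_struct.integers(lo, hi + 1, size=config.n_genes)
    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    isoform_ids = {
        g: [f"{g}.i{j + 1}" for j in range(k)]
        for g, k in zip(gene_ids, n_iso)
    }

    truth = SyntheticTruth()
    n_immune = max(2, round(_IMMUNE_GENE_FRAC * config.n_genes))
    truth.immune_genes = set(
        r_struct.choice(gene_ids, size=n_immune, replace=False))

    multi = [g for g, k in zip(gene_ids, n_iso) if k >= 2]
    eligible_dir = [g for g in multi if g not in truth.immune_genes]
    n_dir = round(config.frac_dir_genes * config.n_genes)
    if n_dir > 0 and len(multi) == 0:
        raise ValueError("no eligible genes: isoform switches need genes "
                         "with >= 2 isoforms")
    if n_dir > len(eligible_dir):
        raise ValueError(
            f"cannot plant {n_dir} switches: only {len(eligible_dir)} "
            "eligible multi-isoform genes")
    dir_genes = sorted(r_struct.choice(eligible_dir, size=n_dir,
                                       replace=False)) if n_dir else []

    eligible_de = [g for g in gene_ids
                   if g not in truth.immune_genes and g not in set(dir_genes)]
    n_de = round(config.frac_de_genes * config.n_genes)
    if n_de > len(eligible_de):
        raise ValueError(f"cannot plant {n_de} expression effects: only "
                         f"{len(eligible_de)} eligible genes")
    de_genes = sorted(r_struct.choice(eligible_de, size=n_de,
                                      replace=False)) if n_de else []
    lfc_lo, lfc_hi = config.de_log2fc_range
    for g in de_genes:
        sign = r_struct.choice([-1.0, 1.0])
        truth.de_genes[g] = float(sign * r_struct.uniform(lfc_lo, lfc_hi))

    # baseline and group-specific isoform proportions
    props_primary: dict[str, np.ndarray] = {}
    props_met: dict[str, np.ndarray] = {}
    for g, k in zip(gene_ids, n_iso):
        p = r_props.dirichlet(np.full(k, _BASELINE_ALPHA))
        props_primary[g] = p
        props_met[g] = p
    for g in dir_genes:
        p = props_primary[g].copy()
        order = np.argsort(p)[::-1]
        src, dst = int(order[0]), int(order[1])
        need = config.dir_delta + _DIR_MARGIN - p[src]
        if need > 0:  # borrow proportionally so the full delta is movable
            rest = 1.0 - p[src]
            p[np.arange(len(p)) != src] *= (rest - need) / rest
            p[src] += need
        props_primary[g] = p
        pm = p.copy()
        pm[src] -= config.dir_delta
        pm[dst] += config.dir_delta
        props_met[g] = pm
        truth.dir_genes[g] = (isoform_ids[g][src], isoform_ids[g][dst],
                              config.dir_delta)

    # gene totals: base abundance x sample noise x batch factor x DE effect
    base = r_totals.lognormal(_GENE_MEANLOG, _GENE_SDLOG, config.n_genes)
    batch_of = r_struct.integers(config.n_batches, size=n_samples)
    batch_eff = (r_totals.normal(0.0, config.batch_sd,
                                 (config.n_genes, config.n_batches))
                 if config.batch_sd > 0
                 else np.zeros((config.n_genes, config.n_batches)))
    noise = r_totals.normal(0.0, _SAMPLE_SDLOG, (config.n_genes, n_samples))
    log_tot = (np.log(base)[:, None] + noise + batch_eff[:, batch_of])
    lfc = np.zeros(config.n_genes)
    for i, g in enumerate(gene_ids):
        if g in truth.de_genes:
            lfc[i] = truth.de_genes[g]
    log_tot += np.log(2.0) * lfc[:, None] * is_met[None, :]
    totals = np.exp(log_tot)  # genes x samples

    # per-sample isoform proportions around the group centers
    conc = config.dirichlet_concentration
    all_iso: list[str] = []
    gene_of: list[str] = []
    values = np.empty((int(n_iso.sum()), n_samples))
    psi_rows: dict[str, np.ndarray] = {}
    row = 0
    for gi, g in enumerate(gene_ids):
        k = n_iso[gi]
        alpha = np.empty((k, n_samples))
        alpha[:, ~is_met] = (conc * props_primary[g])[:, None]
        alpha[:, is_met] = (conc * props_met[g])[:, None]
        draws = r_props.standard_gamma(alpha)
        draws /= draws.sum(axis=0, keepdims=True)
        if g in truth.dir_genes:
            src_iso = truth.dir_genes[g][0]
            psi_rows[g] = draws[isoform_ids[g].index(src_iso)].copy()
        values[row:row + k] = totals[gi] * draws
        all_iso.extend(isoform_ids[g])
        gene_of.extend([g] * k)
        row += k

    # impurity: mix with a fixed contaminant profile
    purity = np.empty(n_samples)
    purity[~is_met] = _beta_draw(r_qc, config.purity_beta_params[0],
                                 config.n_primary)
    purity[is_met] = _beta_draw(r_qc, config.purity_beta_params[1],
                                config.n_metastatic)
    n_inf = round(config.frac_infiltrate_samples * config.n_metastatic)
    met_ids = [s for s, m in zip(sample_ids, is_met) if m]
    truth.infiltrate_samples = set(
        r_qc.choice(met_ids, size=n_inf, replace=False)) if n_inf else set()
    baseline_profile = np.concatenate([
        base[gi] * props_primary[g] for gi, g in enumerate(gene_ids)])
    immune_profile = baseline_profile.copy()
    immune_rows = np.array([g in truth.immune_genes for g in gene_of])
    immune_profile[immune_rows] *= _IMMUNE_FOLD
    inf_cols = np.array([s in truth.infiltrate_samples for s in sample_ids])
    contaminant = np.where(inf_cols[None, :], immune_profile[:, None],
                           baseline_profile[:, None])
    values = purity[None, :] * values + (1.0 - purity[None, :]) * contaminant

    # 3'-fragment bias: conserve gene totals exactly
    bias = np.empty(n_samples)
    bias[~is_met] = _beta_draw(r_qc, config.bias_beta_params[0],
                               config.n_primary)
    bias[is_met] = _beta_draw(r_qc, config.bias_beta_params[1],
                              config.n_metastatic)
    f = config.bias_strength * np.clip((bias - 0.4) / 0.6, 0.0, None)
    row = 0
    for gi, g in enumerate(gene_ids):
        k = n_iso[gi]
        if k >= 2:
            frag = int(r_qc.integers(k))
            truth.fragment_isoforms[g] = isoform_ids[g][frag]
            block = values[row:row + k]
            others = np.arange(k) != frag
            moved = f * block[others].sum(axis=0)
            block[others] *= (1.0 - f)[None, :]
            block[frag] += moved
        row += k

    # detection floor: very low abundances drop out (ties for rank tests)
    values[values < config.detection_floor] = 0.0

    counts = IsoformCountMatrix(
        pd.DataFrame(values, index=all_iso, columns=sample_ids),
        pd.Series(gene_of, index=all_iso),
    )
    meta = pd.DataFrame({
        "sample_type": np.where(is_met, "metastatic", "primary"),
        "batch": [f"b{b + 1}" for b in batch_of],
        "purity": purity,
        "bias_score": bias,
        "subtype": r_qc.choice(["BRAF", "RAS", "NF1", "tripleWT"],
                               p=[0.5, 0.25, 0.15, 0.1], size=n_samples),
        "region": np.where(
            is_met,
            r_qc.choice(["regional_skin", "regional_node", "distant"],
                        p=[0.3, 0.4, 0.3], size=n_samples),
            "primary_site"),
    }, index=pd.Index(sample_ids, name="sample_id"))

    truth.event_map = _plant_events(dir_genes, truth)
    if psi_rows:
        truth.event_psi = pd.DataFrame(
            np.vstack([psi_rows[g] for g in dir_genes]),
            index=list(dir_genes), columns=sample_ids)
    return counts, meta, truth


def _plant_events(dir_genes, truth: SyntheticTruth) -> dict[str, JunctionEvent]:
    """One junction event per switch gene, alternating event types.

    The event tracks the switch's *source* isoform, whose proportion
    (psi) drops by delta in the metastatic group.  For a skipped exon the
    tested fraction is the skip share (1 - psi), expected higher in
    metastatic samples; for an alternative promoter the tested fraction is
    psi itself, expected lower.
    """
    events: dict[str, JunctionEvent] = {}
    for i, g in enumerate(dir_genes):
        start = 10_000 * (i + 1)
        if i % 2 == 0:
            ev = JunctionEvent(g, "skipped_exon", {
                "flank_left": ("chr1", start + 100, start + 200, "+"),
                "flank_right": ("chr1", start + 300, start + 400, "+"),
                "skip": ("chr1", start + 100, start + 400, "+"),
            }, favored_direction="greater")
        else:
            ev = JunctionEvent(g, "alt_promoter", {
                "junction_a": ("chr1", start + 100, start + 500, "+"),
                "junction_b": ("chr1", start + 300, start + 500, "+"),
            }, favored_direction="less")
        events[g] = ev
    return events


def generate_junction_counts(
    ratio_matrix: pd.DataFrame,
    event_map: dict[str, JunctionEvent],
    depth: float,
    seed: Optional[int] = None,
) -> JunctionCountTable:
    """Poisson split-read counts consistent with inclusion proportions.

    ``ratio_matrix`` holds the per-sample inclusion proportion psi of each
    event gene (genes x samples).  For a skipped exon, the two inclusion
    flank junctions are independent Poisson(depth * psi) and the skipping
    junction Poisson(depth * (1 - psi)); two-way events use the analogous
    Poisson(depth * psi) / Poisson(depth * (1 - psi)) pair.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    missing = [g for g in event_map if g not in ratio_matrix.index]
    if missing:
        raise ValueError(f"gene {missing[0]!r} has no row in ratio_matrix")
    rng = np.random.default_rng(seed)
    samples = list(ratio_matrix.columns)
    rows: dict[tuple, np.ndarray] = {}
    for g in event_map:
        ev = event_map[g]
        psi = np.clip(ratio_matrix.loc[g].to_numpy(dtype=float), 0.0, 1.0)
        if ev.event_type == "skipped_exon":
            rows[ev.junctions["flank_left"]] = rng.poisson(depth * psi)
            rows[ev.junctions["flank_right"]] = rng.poisson(depth * psi)
            rows[ev.junctions["skip"]] = rng.poisson(depth * (1.0 - psi))
        else:
            rows[ev.junctions["junction_a"]] = rng.poisson(depth * psi)
            rows[ev.junctions["junction_b"]] = rng.poisson(depth * (1.0 - psi))
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    counts.index = pd.MultiIndex.from_tuples(
        counts.index, names=["chrom", "intron_start", "intron_end", "strand"])
    return JunctionCountTable(counts.astype(int))


# ---------------------------------------------------------------------------
# planted-subgroup scenario for the clustering pipeline
# ---------------------------------------------------------------------------

def generate_subgroup_cohort(
    n_primary: int = 40,
    n_met_per_subgroup: int = 60,
    n_isoforms: int = 60,
    program_size: int = 15,
    effect_fold: float = 5.0,
    noise_sdlog: float = 0.4,
    seed: int = 0,
) -> tuple[IsoformCountMatrix, pd.DataFrame, dict]:
    """Cohort with two metastatic subgroups carrying disjoint programs.

    Each subgroup up-regulates its own ``program_size`` isoforms by
    ``effect_fold`` relative to the primary pool; everything else is shared
    log-normal noise.  Returns counts, metadata and a truth dict with the
    planted ``subgroup`` labels and the two isoform programs (program B
    doubles as an immune-infiltrate program for infiltrate-classification
    checks).
    """
    rng = np.random.default_rng(seed)
    n_met = 2 * n_met_per_subgroup
    sample_ids = ([f"PT{i + 1:03d}" for i in range(n_primary)]
                  + [f"MET{i + 1:03d}" for i in range(n_met)])
    iso_ids = [f"iso{i + 1:03d}" for i in range(n_isoforms)]
    base = rng.lognormal(3.0, 0.8, n_isoforms)
    log_vals = (np.log(base)[:, None]
                + rng.normal(0.0, noise_sdlog, (n_isoforms, len(sample_ids))))
    program_a = iso_ids[:program_size]
    program_b = iso_ids[program_size:2 * program_size]
    subgroup = np.array(
        ["primary"] * n_primary
        + ["met_A"] * n_met_per_subgroup + ["met_B"] * n_met_per_subgroup)
    a_rows = np.isin(iso_ids, program_a)
    b_rows = np.isin(iso_ids, program_b)
    log_vals[np.ix_(a_rows, subgroup == "met_A")] += np.log(effect_fold)
    log_vals[np.ix_(b_rows, subgroup == "met_B")] += np.log(effect_fold)
    values = np.exp(log_vals)
    counts = IsoformCountMatrix(
        pd.DataFrame(values, index=iso_ids, columns=sample_ids),
        pd.Series([f"gene_{i}" for i in iso_ids], index=iso_ids),
    )
    meta = pd.DataFrame({
        "sample_type": np.where(subgroup == "primary", "primary",
                                "metastatic"),
        "batch": "b1",
        "purity": 1.0,
        "bias_score": 0.0,
        "subtype": "unknown",
        "region": "unknown",
    }, index=pd.Index(sample_ids, name="sample_id"))
    truth = {
        "subgroup": pd.Series(subgroup, index=sample_ids),
        "program_a": program_a,
        "program_b": program_b,
        "infiltrate_samples": set(np.array(sample_ids)[subgroup == "met_B"]),
    }
    return counts, meta, truth


def simulate_to_dir(config: CohortConfig, out_dir) -> None:
    """Generate a cohort and write counts/metadata/truth/junctions files."""
    from pathlib import Path
    from .io import write_isoform_counts, write_metadata
    from .junctions import write_junction_counts, write_events

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, meta, truth = generate_cohort(config)
    write_isoform_counts(counts, out / "counts.tsv")
    write_metadata(meta, out / "metadata.tsv")
    truth.to_json(out / "truth.json")
    if truth.event_map and truth.event_psi is not None:
        junc_seed = int(np.random.SeedSequence(config.seed).spawn(5)[4]
                        .generate_state(1)[0] % (2**31))
        table = generate_junction_counts(
            truth.event_psi, truth.event_map, config.junction_depth,
            seed=junc_seed)
        write_junction_counts(table, out / "junctions.tsv")
        write_events(list(truth.event_map.values()), out / "events.tsv")
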