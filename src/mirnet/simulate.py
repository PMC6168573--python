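"""Synthetic two-layer study generator with a serialized planted truth.

Generates a complete desk-scale myocardial-infarction-style study — mRNA and
miRNA negative-binomial count matrices over sham/MI groups at three disease
stages, a TargetScan-style family->gene prediction table, a miRNA family
registry, flat GO annotations and a GMT gene-set collection — together with a
``PlantedTruth`` document recording exactly which effects were planted, so
every downstream filter of the integration pipeline has a known answer.

What the generator emulates:

* negative-binomial counts with small dispersion, giving within-group
  replicate correlations of log2 values above 0.99;
* a heavy-tailed miRNA abundance law (truncated power law) rescaled so the
  top-50 mean-RPM share hits a configured target (default 0.96);
* stage-specific differential-expression programs (large early/middle,
  small at the end stage);
* planted miRNA families whose predicted targets move opposite to the
  family at every stage, plus one decoy family per integration filter.

All randomness flows from ``SimulationConfig.seed`` through a fixed
stream-splitting scheme (one child stream per output artifact), so every
artifact is bit-identical across runs and independent of which other
artifacts are generated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .containers import (
    CountMatrix,
    FamilyRegistry,
    GeneSet,
    GeneSetCollection,
    GOAnnotationTable,
    MirnetError,
    SampleDesign,
    SPECIES,
    TargetPredictionTable,
)

# GO terms the candidate cascade intersects with; direction pairing follows
# the anti-co-expression logic (an up-regulated family suppresses
# anti-apoptotic genes, so its candidates carry the "negative regulation" term).
POSITIVE_APOPTOSIS_TERM = "positive regulation of apoptotic process"
NEGATIVE_APOPTOSIS_TERM = "negative regulation of apoptotic process"

#: decoy failure modes -> the integration filter each one must be eliminated at
DECOY_MODES = ("conservation", "target_filter", "de_all_stages", "min_conserved_targets", "top_k")

# fixed child-stream indices of the seed-splitting scheme
_STREAM_TRUTH, _STREAM_MRNA, _STREAM_MIRNA, _STREAM_TARGETS, _STREAM_ANNOT = range(5)


@dataclass(frozen=True)
class DecoySpec:
    """One decoy family, designed to fail exactly one integration filter."""

    failure: str
    direction: str = "down"
    n_weak_targets: int = 4  # conserved-site targets at the weak stage (min_conserved_targets mode)
    weak_stage_index: int = 1

    def __post_init__(self) -> None:
        if self.failure not in DECOY_MODES:
            raise MirnetError(f"unknown decoy failure mode {self.failure!r}")
        if self.direction not in ("up", "down"):
            raise MirnetError("decoy direction must be up or down")


def default_decoys() -> list[DecoySpec]:
    """One decoy per integration filter (the full negative-control panel)."""
    return [
        DecoySpec("conservation", "up"),
        DecoySpec("target_filter", "down"),
        DecoySpec("de_all_stages", "down"),
        DecoySpec("min_conserved_targets", "down"),
        DecoySpec("top_k", "up"),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-generation parameters.

    Defaults are the package's reference desk-scale study: 2,000 genes,
    300 miRNAs, three stages with 3 replicates per condition, strong planted
    effects (log2FC 2.5) on a low-dispersion negative-binomial background,
    DE programs of 15%/20%/2% of genes across the stages, and a miRNA
    abundance law concentrated so the top 50 miRNAs carry 96% of reads.
    """

    n_genes: int = 2000
    n_mirnas: int = 300
    stages: tuple[str, ...] = ("1D", "1W", "8W")
    n_replicates_per_group: int = 3
    nb_dispersion: float = 0.005
    library_size_mean: float = 5e6  # mRNA reads per library
    mirna_library_size_mean: float = 2e6
    de_fraction_per_stage: tuple[float, ...] = (0.15, 0.20, 0.02)
    de_log2fc_magnitude: float = 2.5
    top_share_target: float = 0.96
    n_planted_families: int = 2
    targets_per_family_per_stage: int = 12
    decoy_family_specs: tuple[DecoySpec, ...] = field(default_factory=lambda: tuple(default_decoys()))
    n_background_demirs: int = 60
    n_candidates_per_family: tuple[int, ...] = (9, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_mirnas < 1 or self.n_replicates_per_group < 1:
            raise MirnetError("all counts must be >= 1")
        if len(self.stages) != len(set(self.stages)):
            raise MirnetError("stage labels must be unique")
        if len(self.de_fraction_per_stage) != len(self.stages):
            raise MirnetError("need one de_fraction per stage")
        if any(not (0.0 <= f <= 1.0) for f in self.de_fraction_per_stage):
            raise MirnetError("de_fraction_per_stage entries must lie in [0, 1]")
        if not (0.0 < self.top_share_target <= 1.0):
            raise MirnetError("top_share_target must lie in (0, 1]")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0 or self.mirna_library_size_mean <= 0:
            raise MirnetError("dispersion and library sizes must be positive")
        if self.de_log2fc_magnitude <= 0:
            raise MirnetError("de_log2fc_magnitude must be positive")
        if self.n_planted_families > 0 and self.targets_per_family_per_stage < 10:
            raise MirnetError("planted families need >= 10 targets per stage to be positives")
        if self.n_planted_families > len(self.n_candidates_per_family):
            raise MirnetError("need one n_candidates entry per planted family")

    @staticmethod
    def null(seed: int = 0, n_genes: int = 2000, n_mirnas: int = 300) -> "SimulationConfig":
        """A no-effect configuration: no DE programs, no planted or decoy families."""
        return SimulationConfig(
            n_genes=n_genes,
            n_mirnas=n_mirnas,
            de_fraction_per_stage=(0.0, 0.0, 0.0),
            n_planted_families=0,
            decoy_family_specs=(),
            n_background_demirs=0,
            n_candidates_per_family=(),
            seed=seed,
        )

    def rng(self, stream: int) -> np.random.Generator:
        """Child RNG for one artifact stream (fixed splitting scheme)."""
        children = np.random.SeedSequence(self.seed).spawn(5)
        return np.random.default_rng(children[stream])


@dataclass
class PlantedTruth:
    """Everything the generator planted, for end-to-end verification.

    ``de_genes_by_stage`` / ``de_mirnas_by_stage`` map stage -> {"up": [...],
    "down": [...]}. ``families`` records, per family, its members, direction,
    DE stages, species conservation and role. ``family_targets`` maps
    family -> stage -> {"conserved": [...], "non_conserved": [...]} planted
    passing edges. ``decoy_families`` maps decoy family -> the single filter
    it must fail.
    """

    stages: list[str]
    de_genes_by_stage: dict[str, dict[str, list[str]]]
    de_mirnas_by_stage: dict[str, dict[str, list[str]]]
    families: dict[str, dict]
    family_targets: dict[str, dict[str, dict[str, list[str]]]]
    planted_families: list[str]
    planted_candidates: dict[str, list[str]]
    decoy_families: dict[str, str]

    def __post_init__(self) -> None:
        overlap = set(self.planted_families) & set(self.decoy_families)
        if overlap:
            raise MirnetError(f"families cannot be both planted and decoy: {sorted(overlap)}")

    def gene_direction(self, gene: str, stage: str) -> str:
        by = self.de_genes_by_stage.get(stage, {})
        if gene in by.get("up", []):
            return "up"
        if gene in by.get("down", []):
            return "down"
        return "ns"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(doc: dict) -> "PlantedTruth":
        return PlantedTruth(**doc)


def _gene_ids(n: int) -> list[str]:
    return [f"gene{i:05d}" for i in range(1, n + 1)]


def _mirna_ids(n: int) -> list[str]:
    return [f"mir{i:04d}" for i in range(1, n + 1)]


def plan_truth(config: SimulationConfig) -> PlantedTruth:
    """Lay out the planted effects implied by ``config`` (deterministic)."""
    rng = config.rng(_STREAM_TRUTH)
    stages = list(config.stages)
    genes = _gene_ids(config.n_genes)
    mirnas = _mirna_ids(config.n_mirnas)

    # --- miRNA families -----------------------------------------------------
    # Abundance rank r (0 = most abundant) is implicit in the miRNA id order.
    # Planted and decoy families sit at moderate ranks: high enough to be in
    # the top-50 DEmiRs, but clear of the few dominating miRNAs so the
    # abundance law is not distorted by their fold changes. The top_k decoy
    # sits deep in the tail.
    families: dict[str, dict] = {}
    reserved: set[int] = set()

    def take_ranks(ranks: list[int]) -> list[str]:
        for r in ranks:
            if r in reserved or r >= config.n_mirnas:
                raise MirnetError(f"abundance rank {r} unavailable (n_mirnas too small?)")
            reserved.add(r)
        return [mirnas[r] for r in ranks]

    planted_ids = [f"fam-p{i + 1}" for i in range(config.n_planted_families)]
    planted_dirs = ["down" if i % 2 == 0 else "up" for i in range(config.n_planted_families)]
    base_rank = 7
    for i, (fam, direction) in enumerate(zip(planted_ids, planted_dirs)):
        n_members = 4 if i == 0 else 1  # first family is miR-30-like (4 members)
        ranks = [base_rank + 4 * j for j in range(n_members)]
        base_rank = max(ranks) + 2 if n_members > 1 else base_rank + 2
        families[fam] = {
            "members": take_ranks(ranks),
            "direction": direction,
            "stages": stages,
            "conserved": list(SPECIES),
            "role": "planted",
        }

    decoy_map: dict[str, str] = {}
    next_rank = max(reserved) + 2 if reserved else 7
    for spec in config.decoy_family_specs:
        fam = f"fam-d-{spec.failure}"
        if fam in decoy_map or fam in families:
            raise MirnetError(f"duplicate decoy failure mode {spec.failure!r}")
        if spec.failure == "top_k":
            rank = config.n_mirnas - 20
            if rank <= 50:
                raise MirnetError("n_mirnas too small to park a decoy below the top 50")
            ranks = [rank]
        else:
            while next_rank in reserved:
                next_rank += 1
            ranks = [next_rank]
        de_stages = stages[:-1] if spec.failure == "de_all_stages" else stages
        conserved = ["mouse", "rat"] if spec.failure == "conservation" else list(SPECIES)
        families[fam] = {
            "members": take_ranks(ranks),
            "direction": spec.direction,
            "stages": list(de_stages),
            "conserved": conserved,
            "role": "decoy",
            "failure": spec.failure,
            "n_weak_targets": spec.n_weak_targets,
            "weak_stage": stages[spec.weak_stage_index],
        }
        decoy_map[fam] = spec.failure

    # Background DEmiRs: enough of them, at higher abundance than the top_k
    # decoy, that the top-50 DEmiR cut actually excludes that decoy. Each is
    # DE at only 1-2 stages, so all die at the first cascade filter.
    free_ranks = [r for r in range(5, min(120, config.n_mirnas)) if r not in reserved]
    n_bg = min(config.n_background_demirs, len(free_ranks))
    bg_ranks = sorted(rng.choice(free_ranks, size=n_bg, replace=False).tolist())
    for r in bg_ranks:
        mirna = mirnas[r]
        fam = f"fam-b-{mirna}"
        direction = str(rng.choice(["up", "down"]))
        n_stages = int(rng.integers(1, 3))  # 1 or 2 stages, never all
        de_stages = sorted(
            rng.choice(len(stages), size=n_stages, replace=False).tolist()
        )
        families[fam] = {
            "members": take_ranks([r]),
            "direction": direction,
            "stages": [stages[i] for i in de_stages],
            "conserved": list(SPECIES),
            "role": "background",
        }

    de_mirnas_by_stage = {s: {"up": [], "down": []} for s in stages}
    for fam, info in families.items():
        for s in info["stages"]:
            de_mirnas_by_stage[s][info["direction"]].extend(info["members"])
    for s in stages:
        for d in ("up", "down"):
            de_mirnas_by_stage[s][d] = sorted(de_mirnas_by_stage[s][d])

    # --- gene-level DE programs and planted targets -------------------------
    # Targets of each planted/decoy family are disjoint gene blocks, DE at
    # exactly one stage, moving opposite to the family.
    gene_pool = list(genes)
    rng.shuffle(gene_pool)
    cursor = 0

    def take_genes(k: int) -> list[str]:
        nonlocal cursor
        if cursor + k > len(gene_pool):
            raise MirnetError("n_genes too small for the planted target layout")
        out = gene_pool[cursor : cursor + k]
        cursor += k
        return out

    de_genes: dict[str, dict[str, set[str]]] = {s: {"up": set(), "down": set()} for s in stages}
    family_targets: dict[str, dict[str, dict[str, list[str]]]] = {}
    for fam, info in families.items():
        if info["role"] == "background":
            continue
        opposite = "up" if info["direction"] == "down" else "down"
        per_stage: dict[str, dict[str, list[str]]] = {}
        for s in stages:
            if info["role"] == "decoy" and info["failure"] == "min_conserved_targets" and s == info["weak_stage"]:
                conserved = take_genes(info["n_weak_targets"])
                non_conserved = take_genes(
                    config.targets_per_family_per_stage - info["n_weak_targets"]
                )
            else:
                conserved = take_genes(config.targets_per_family_per_stage)
                non_conserved = []
            for g in conserved + non_conserved:
                de_genes[s][opposite].add(g)
            per_stage[s] = {
                "conserved": sorted(conserved),
                "non_conserved": sorted(non_conserved),
            }
        family_targets[fam] = per_stage

    # Fill each stage's DE program up to its configured fraction with
    # background genes (never the planted target blocks); a gene keeps one
    # direction across all stages where it is DE.
    background_genes = gene_pool[cursor:]
    gene_sign = {g: str(rng.choice(["up", "down"])) for g in background_genes}
    for s, frac in zip(stages, config.de_fraction_per_stage):
        quota = int(round(frac * config.n_genes))
        have = len(de_genes[s]["up"]) + len(de_genes[s]["down"])
        need = max(0, quota - have)
        need = min(need, len(background_genes))
        if need:
            picked = rng.choice(len(background_genes), size=need, replace=False)
            for i in picked:
                g = background_genes[i]
                de_genes[s][gene_sign[g]].add(g)

    de_genes_by_stage = {
        s: {"up": sorted(v["up"]), "down": sorted(v["down"])} for s, v in de_genes.items()
    }

    # --- apoptosis candidates ------------------------------------------------
    planted_candidates: dict[str, list[str]] = {}
    for i, fam in enumerate(planted_ids):
        n_cand = config.n_candidates_per_family[i]
        all_targets = sorted(
            {g for s in stages for g in family_targets[fam][s]["conserved"]}
        )
        if n_cand > len(all_targets):
            raise MirnetError(f"family {fam}: more candidates requested than planted targets")
        picked = rng.choice(len(all_targets), size=n_cand, replace=False)
        planted_candidates[fam] = sorted(all_targets[i] for i in picked)

    return PlantedTruth(
        stages=stages,
        de_genes_by_stage=de_genes_by_stage,
        de_mirnas_by_stage=de_mirnas_by_stage,
        families=families,
        family_targets=family_targets,
        planted_families=planted_ids,
        planted_candidates=planted_candidates,
        decoy_families=decoy_map,
    )


def make_design(config: SimulationConfig) -> SampleDesign:
    rows = []
    for stage in config.stages:
        for condition in ("sham", "MI"):
            for rep in range(1, config.n_replicates_per_group + 1):
                rows.append(
                    {
                        "sample_id": f"{condition}_{stage}_r{rep}",
                        "condition": condition,
                        "stage": stage,
                        "replicate": rep,
                    }
                )
    return SampleDesign(pd.DataFrame(rows))


def _check_truth(config: SimulationConfig, truth: PlantedTruth) -> None:
    if list(config.stages) != truth.stages:
        raise MirnetError("truth stages do not match config stages")
    n_planted = len(truth.planted_families)
    if n_planted != config.n_planted_families:
        raise MirnetError(
            f"truth has {n_planted} planted families, config expects {config.n_planted_families}"
        )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (gamma-Poisson)."""
    mean = np.clip(mean, 1e-12, None)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def _de_multipliers(
    truth: PlantedTruth,
    feature_ids: list[str],
    stage: str,
    magnitude: float,
    by_stage: dict[str, dict[str, list[str]]],
) -> np.ndarray:
    mult = np.ones(len(feature_ids))
    index = {f: i for i, f in enumerate(feature_ids)}
    for f in by_stage.get(stage, {}).get("up", []):
        if f in index:
            mult[index[f]] = 2.0**magnitude
    for f in by_stage.get(stage, {}).get("down", []):
        if f in index:
            mult[index[f]] = 2.0**-magnitude
    return mult


def simulate_mrna_counts(config: SimulationConfig, truth: PlantedTruth) -> CountMatrix:
    """Negative-binomial mRNA counts with the planted per-stage DE program."""
    _check_truth(config, truth)
    rng = config.rng(_STREAM_MRNA)
    design = make_design(config)
    genes = _gene_ids(config.n_genes)

    lengths = pd.Series(
        rng.integers(500, 5001, size=config.n_genes), index=pd.Index(genes, name="feature_id")
    )
    weights = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_genes)
    # Planted target genes are expressed genes: floor their base abundance at
    # the median so a 2^magnitude shift always clears the fold-change rule
    # (the +1 pseudocount compresses fold changes of barely expressed genes).
    target_genes: set[str] = set()
    for per_stage in truth.family_targets.values():
        for stage_sets in per_stage.values():
            for kind in ("conserved", "non_conserved"):
                target_genes.update(stage_sets[kind])
    if target_genes:
        floor = float(np.median(weights))
        idx = [i for i, g in enumerate(genes) if g in target_genes]
        weights[idx] = np.maximum(weights[idx], floor)
    weights /= weights.sum()

    cols = {}
    for _, row in design.table.iterrows():
        lib = config.library_size_mean * rng.lognormal(0.0, 0.05)
        mult = (
            _de_multipliers(
                truth, genes, row["stage"], config.de_log2fc_magnitude, truth.de_genes_by_stage
            )
            if row["condition"] == "MI"
            else np.ones(config.n_genes)
        )
        mean = weights * mult * lib
        cols[row["sample_id"]] = _nb_sample(rng, mean, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="feature_id"))
    return CountMatrix(counts, design, "mRNA", lengths)


def _mirna_weights(config: SimulationConfig, truth: PlantedTruth) -> np.ndarray:
    """Truncated power-law abundance rescaled so the expected top-50
    mean-RPM share (DE effects included) hits ``top_share_target``."""
    n, k = config.n_mirnas, 50
    if config.top_share_target < 1.0 and n < k:
        raise MirnetError("top-50 share target needs at least 50 miRNAs")
    mirnas = _mirna_ids(n)
    conditions = [("sham", s) for s in config.stages] + [("MI", s) for s in config.stages]

    def expected_share(alpha: float) -> float:
        w = np.arange(1, n + 1, dtype=float) ** -alpha
        shares = np.zeros(n)
        for condition, stage in conditions:
            mult = (
                _de_multipliers(
                    truth, mirnas, stage, config.de_log2fc_magnitude, truth.de_mirnas_by_stage
                )
                if condition == "MI"
                else np.ones(n)
            )
            p = w * mult
            shares += p / p.sum()
        shares /= len(conditions)
        top = np.sort(shares)[::-1][:k].sum()
        return top / shares.sum()

    lo, hi = 0.0, 6.0
    if expected_share(hi) < config.top_share_target - 1e-6:
        raise MirnetError(
            f"top_share_target={config.top_share_target} unattainable with n_mirnas={n}"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected_share(mid) < config.top_share_target:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    w = np.arange(1, n + 1, dtype=float) ** -alpha
    return w / w.sum()


def simulate_mirna_counts(config: SimulationConfig, truth: PlantedTruth) -> CountMatrix:
    """Heavy-tailed miRNA counts; planted families move consistently at
    every DE stage, decoys violate exactly their assigned filter."""
    _check_truth(config, truth)
    rng = config.rng(_STREAM_MIRNA)
    design = make_design(config)
    mirnas = _mirna_ids(config.n_mirnas)
    weights = _mirna_weights(config, truth)

    cols = {}
    for _, row in design.table.iterrows():
        lib = config.mirna_library_size_mean * rng.lognormal(0.0, 0.05)
        mult = (
            _de_multipliers(
                truth, mirnas, row["stage"], config.de_log2fc_magnitude, truth.de_mirnas_by_stage
            )
            if row["condition"] == "MI"
            else np.ones(config.n_mirnas)
        )
        mean = weights * mult * lib
        cols[row["sample_id"]] = _nb_sample(rng, mean, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(mirnas, name="feature_id"))
    return CountMatrix(counts, design, "miRNA")


def simulate_families(config: SimulationConfig, truth: PlantedTruth) -> FamilyRegistry:
    """Family registry: planted/decoy/background families from the truth,
    singleton families for every remaining miRNA."""
    _check_truth(config, truth)
    rows = []
    assigned = set()
    for fam, info in truth.families.items():
        for m in info["members"]:
            rows.append(
                {
                    "mirna_id": m,
                    "family_id": fam,
                    "conserved_mouse": "mouse" in info["conserved"],
                    "conserved_rat": "rat" in info["conserved"],
                    "conserved_human": "human" in info["conserved"],
                }
            )
            assigned.add(m)
    for m in _mirna_ids(config.n_mirnas):
        if m not in assigned:
            rows.append(
                {
                    "mirna_id": m,
                    "family_id": f"fam-s-{m}",
                    "conserved_mouse": True,
                    "conserved_rat": True,
                    "conserved_human": False,
                }
            )
    df = pd.DataFrame(rows).sort_values("mirna_id", kind="stable").reset_index(drop=True)
    return FamilyRegistry(df)


def simulate_target_table(config: SimulationConfig, truth: PlantedTruth) -> TargetPredictionTable:
    """Planted passing edges plus background edges across the WCSP range.

    Planted conserved-site edges carry WCSP > 50, >= 1 seed site and
    all-species site conservation (except the conservation decoy, whose rows
    all lack the human flag). The target_filter decoy's rows all sit at
    WCSP <= 50. Background rows sample WCSP uniformly on [0, 100].
    """
    _check_truth(config, truth)
    rng = config.rng(_STREAM_TARGETS)
    rows = []
    for fam, per_stage in truth.family_targets.items():
        info = truth.families[fam]
        failure = info.get("failure")
        human_flag = failure != "conservation"
        seen: set[str] = set()
        for s in truth.stages:
            for kind in ("conserved", "non_conserved"):
                for g in per_stage[s][kind]:
                    if g in seen:
                        continue
                    seen.add(g)
                    if failure == "target_filter":
                        wcsp = float(rng.uniform(0, 50))
                    else:
                        wcsp = float(rng.uniform(55, 100))
                    rows.append(
                        {
                            "family_id": fam,
                            "gene_id": g,
                            "wcsp": round(wcsp, 3),
                            "seed_sites": int(rng.integers(1, 4)),
                            "conserved_mouse": True,
                            "conserved_rat": True,
                            "conserved_human": human_flag,
                            "conserved_site": kind == "conserved",
                        }
                    )
    # background edges: random singleton families x random genes
    genes = _gene_ids(config.n_genes)
    bg_fams = [f"fam-s-{m}" for m in _mirna_ids(config.n_mirnas)]
    n_bg = 2500
    seen_pairs = set()
    for _ in range(n_bg):
        fam = bg_fams[int(rng.integers(0, len(bg_fams)))]
        g = genes[int(rng.integers(0, len(genes)))]
        if (fam, g) in seen_pairs:
            continue
        seen_pairs.add((fam, g))
        rows.append(
            {
                "family_id": fam,
                "gene_id": g,
                "wcsp": round(float(rng.uniform(0, 100)), 3),
                "seed_sites": int(rng.integers(0, 4)),
                "conserved_mouse": bool(rng.random() < 0.9),
                "conserved_rat": bool(rng.random() < 0.7),
                "conserved_human": bool(rng.random() < 0.6),
                "conserved_site": bool(rng.random() < 0.5),
            }
        )
    df = (
        pd.DataFrame(rows)
        .sort_values(["family_id", "gene_id"], kind="stable")
        .reset_index(drop=True)
    )
    return TargetPredictionTable(df)


def simulate_annotations(
    config: SimulationConfig, truth: PlantedTruth
) -> tuple[GOAnnotationTable, GeneSetCollection]:
    """Flat GO table + hallmark-like GMT collection.

    The two apoptosis terms exist and contain exactly the planted candidates
    among each planted family's target genes (background members are drawn
    away from all planted target blocks, so the candidate cascade's final
    intersection recovers the planted sets exactly).
    """
    _check_truth(config, truth)
    rng = config.rng(_STREAM_ANNOT)
    genes = _gene_ids(config.n_genes)
    planted_target_genes: set[str] = set()
    for per_stage in truth.family_targets.values():
        for s in truth.stages:
            for kind in ("conserved", "non_conserved"):
                planted_target_genes.update(per_stage[s][kind])
    safe_genes = sorted(set(genes) - planted_target_genes)

    def background(n: int) -> list[str]:
        idx = rng.choice(len(safe_genes), size=min(n, len(safe_genes)), replace=False)
        return [safe_genes[i] for i in sorted(idx)]

    rows = []
    term_members: dict[str, list[str]] = {
        POSITIVE_APOPTOSIS_TERM: background(50),
        NEGATIVE_APOPTOSIS_TERM: background(50),
    }
    for i, fam in enumerate(truth.planted_families):
        direction = truth.families[fam]["direction"]
        # an up family's candidates come from down-DEG targets -> "negative
        # regulation of apoptotic process"; a down family's from up-DEG
        # targets -> "positive regulation".
        term = NEGATIVE_APOPTOSIS_TERM if direction == "up" else POSITIVE_APOPTOSIS_TERM
        term_members[term] = sorted(set(term_members[term]) | set(truth.planted_candidates[fam]))
    generic_terms = [
        "inflammatory response",
        "fatty acid metabolism",
        "oxidative phosphorylation",
        "extracellular matrix organization",
        "cardiac muscle contraction",
        "response to hypoxia",
        "TGF-beta signaling",
        "cell cycle",
    ]
    for t in generic_terms:
        term_members[t] = background(int(rng.integers(30, 120)))
    for term in sorted(term_members):
        for g in sorted(term_members[term]):
            rows.append({"gene_id": g, "term": term})
    go = GOAnnotationTable(pd.DataFrame(rows))

    sets = []
    for s in truth.stages:
        for d in ("up", "down"):
            members = truth.de_genes_by_stage[s][d]
            if len(members) >= 15:
                idx = rng.choice(len(members), size=min(30, len(members)), replace=False)
                sets.append(
                    GeneSet(
                        f"SYNSET_{d.upper()}_{s}",
                        f"planted {d}-regulated genes at stage {s}",
                        frozenset(members[i] for i in sorted(idx)),
                    )
                )
    for i in range(12):
        size = int(rng.integers(15, 201))
        idx = rng.choice(len(genes), size=size, replace=False)
        sets.append(
            GeneSet(
                f"SYNSET_RANDOM_{i + 1:02d}",
                "random background set",
                frozenset(genes[j] for j in sorted(idx)),
            )
        )
    return go, GeneSetCollection(sets)


@dataclass
class StudyBundle:
    """Paths to a generated on-disk study plus its in-memory truth."""

    outdir: Path
    mrna_counts: Path
    mirna_counts: Path
    design: Path
    targets: Path
    families: Path
    go_annotations: Path
    gene_sets: Path
    truth_file: Path
    truth: PlantedTruth

    def data_files(self) -> list[Path]:
        return [
            self.mrna_counts,
            self.mirna_counts,
            self.design,
            self.targets,
            self.families,
            self.go_annotations,
            self.gene_sets,
        ]


def generate_study(config: SimulationConfig, outdir: str | Path) -> StudyBundle:
    """Generate and write the full study: 7 data files + the truth document."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = plan_truth(config)
    design = make_design(config)
    mrna = simulate_mrna_counts(config, truth)
    mirna = simulate_mirna_counts(config, truth)
    registry = simulate_families(config, truth)
    targets = simulate_target_table(config, truth)
    go, gmt = simulate_annotations(config, truth)

    bundle = StudyBundle(
        outdir=outdir,
        mrna_counts=outdir / "mrna_counts.tsv",
        mirna_counts=outdir / "mirna_counts.tsv",
        design=outdir / "design.tsv",
        targets=outdir / "targets.tsv",
        families=outdir / "families.tsv",
        go_annotations=outdir / "go_annotations.tsv",
        gene_sets=outdir / "gene_sets.gmt",
        truth_file=outdir / "truth.yaml",
        truth=truth,
    )
    io.write_design(design, bundle.design)
    io.write_counts(mrna, bundle.mrna_counts)
    io.write_counts(mirna, bundle.mirna_counts)
    io.write_families(registry, bundle.families)
    io.write_predictions(targets, bundle.targets)
    io.write_go_annotations(go, bundle.go_annotations)
    io.write_gmt(gmt, bundle.gene_sets)
    io.write_yaml(truth.to_dict(), bundle.truth_file)
    return bundle


def load_truth(path: str | Path) -> PlantedTruth:
    return PlantedTruth.from_dict(io.read_yaml(path))
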