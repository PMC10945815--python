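"""End-to-end orchestration: simulate or load → normalize → divergence → tests.

A single :class:`RunConfig` drives the whole analysis; identical
(config, seed) pairs produce identical output bundles. Outputs are written
as labeled CSV matrices plus a machine-readable ``summary.json`` that
records every statistic together with the seed, permutation count and
scheme that produced it, and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import divergence as dv
from . import phylostats as ps
from .normalize import ProfileTable, SampleTable, growth_state, normalize_pipeline
from .synthetic_data import SimulatedDataset, SimulationConfig, simulate_dataset, simulate_yield_profiles
from .treeio import Phylogeny, patristic_distance_matrix, read_newick

__all__ = ["RunConfig", "run_full_analysis", "count_pairs"]

logger = logging.getLogger("phylometab")

SUMMARY_SCHEMA_VERSION = 1


def count_pairs(n: int) -> int:
    """Number of unordered pairs among n labels, n(n-1)/2."""
    if n < 2:
        raise ValueError("need at least two labels to form a pair")
    return n * (n - 1) // 2


@dataclass
class RunConfig:
    """Everything a full analysis run needs.

    Either ``simulation`` is set (synthetic study) or the input paths are;
    mixing is allowed (e.g. real tree with simulated yields is not a
    supported combination and fails validation).
    """

    simulation: SimulationConfig | None = None
    tree_path: str | None = None
    targeted_path: str | None = None
    untargeted_path: str | None = None
    yields_path: str | None = None
    channels: tuple[str, ...] = ("targeted", "untargeted")
    level: str = "population"
    n_permutations: int = 9_999
    alpha: float = 0.05
    scheme: str = "phylogenetic"
    seed: int = 0
    exclude_populations: tuple[str, ...] = ()
    use_growth_covariate: bool = False
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.simulation is None and self.tree_path is None:
            raise ValueError("either a simulation config or input paths are required")
        if self.simulation is not None and self.tree_path is not None:
            raise ValueError("simulation and file inputs are mutually exclusive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        for key in ("channels", "exclude_populations"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig) -> tuple[Phylogeny, dict[str, SampleTable],
                                             pd.DataFrame | None, SimulatedDataset | None]:
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        dataset = simulate_dataset(sim)
        tables = {"targeted": dataset.targeted, "untargeted": dataset.untargeted}
        yields, _ = simulate_yield_profiles(
            dataset.tree.tip_labels, seed=config.seed + 1)
        return dataset.tree, tables, yields, dataset
    tree = read_newick(config.tree_path)
    tables: dict[str, SampleTable] = {}
    if config.targeted_path:
        tables["targeted"] = SampleTable.from_csv(config.targeted_path)
    if config.untargeted_path:
        tables["untargeted"] = SampleTable.from_csv(config.untargeted_path)
    yields = pd.read_csv(config.yields_path, index_col=0) if config.yields_path else None
    return tree, tables, yields, None


def _validate_labels(tree: Phylogeny, tables: Mapping[str, SampleTable]) -> None:
    problems = []
    tips = set(tree.tip_labels)
    for channel, table in tables.items():
        pops = set(table.meta.loc[~table.is_qc, "population"])
        missing = sorted(pops - tips)
        if missing:
            problems.append(f"{channel}: populations absent from tree: {missing}")
    if problems:
        raise ValueError("label validation failed:\n" + "\n".join(problems))


def _channel_results(
    channel: str,
    table: SampleTable,
    tree: Phylogeny,
    groups: Mapping[str, str],
    clades: Sequence[Sequence[str]] | None,
    config: RunConfig,
    rng_seed: int,
) -> dict[str, Any]:
    """Normalize one channel and run the comparative statistics on it."""
    strain_profiles, report = normalize_pipeline(table, channel=channel, level="strain")
    meta = table.meta.loc[~table.is_qc]
    strain_to_pop = meta.drop_duplicates("strain").set_index("strain")["population"]
    logger.info("%s: %d strains x %d metabolites after normalization",
                channel, *strain_profiles.levels.shape)

    pop_div = dv.group_divergence(strain_profiles, strain_to_pop.to_dict())
    keep = [l for l in pop_div.labels if l not in set(config.exclude_populations)]
    pop_div = pop_div.reorder(keep)
    labels, P = patristic_distance_matrix(tree, pop_div.labels)
    patristic = dv.DistanceMatrix(labels, P, kind="patristic")
    adjusted = dv.phylo_adjusted_divergence(pop_div, patristic)

    out: dict[str, Any] = {
        "n_metabolites": strain_profiles.levels.shape[1],
        "n_strains": strain_profiles.levels.shape[0],
        "n_populations": len(pop_div.labels),
        "n_population_pairs": count_pairs(len(pop_div.labels)),
    }

    # Mantel: divergence vs phylogenetic distance, within wild and within
    # domesticated label subsets
    for tag, subset in (
        ("wild", [l for l in pop_div.labels if groups.get(l) == "wild"]),
        ("domesticated", [l for l in pop_div.labels if groups.get(l) == "domesticated"]),
        ("all", list(pop_div.labels)),
    ):
        if len(subset) < 4:
            continue
        res = ps.mantel_test(
            pop_div.reorder(subset), patristic.reorder(subset),
            n_permutations=config.n_permutations, scheme=config.scheme,
            tree=tree, seed=rng_seed,
        )
        out[f"mantel_{tag}"] = dataclasses.asdict(res)

    # rate comparison: adjusted divergence of domesticated vs wild pairs
    if clades is not None:
        eligible = dv.wild_pairs(groups, exclude=config.exclude_populations)
        eligible += dv.same_clade_pairs(clades)
        eligible = [p for p in eligible
                    if p[0] in pop_div.labels and p[1] in pop_div.labels]
        for tag, matrix in (("adjusted", adjusted), ("raw", pop_div)):
            res = ps.group_ratio_permutation_test(
                matrix, {l: groups[l] for l in pop_div.labels},
                n_permutations=config.n_permutations, seed=rng_seed,
                eligible_pairs=eligible,
            )
            out[f"ratio_test_{tag}"] = dataclasses.asdict(res)

    # per-metabolite signature scan (population-level profiles)
    pop_profiles, _ = normalize_pipeline(table, channel=channel, level="population")
    covariate = None
    if config.use_growth_covariate:
        gs = growth_state(meta["od_inoc"], meta["od_samp"], meta["od_stat"])
        covariate = gs.groupby(meta["population"]).mean()
    scan = ps.domestication_signature_scan(
        pop_profiles, tree, groups, covariate=covariate,
        alpha=config.alpha, exclude=config.exclude_populations,
    )
    out["signature"] = {
        "n_significant": int(scan["significant"].sum()),
        "n_tested": int(len(scan)),
        "alpha": config.alpha,
        "significant_metabolites": sorted(scan.index[scan["significant"]]),
    }
    return out | {"_scan": scan, "_profiles": pop_profiles, "_divergence": pop_div,
                  "_adjusted": adjusted, "_patristic": patristic}


def _yield_results(
    yields: pd.DataFrame,
    pop_div: dv.DistanceMatrix,
    n_permutations: int,
    seed: int,
) -> dict[str, Any]:
    """Yield identity classification and the identical-vs-different rate test."""
    ydist, identical = dv.yield_distance_and_identity(yields)
    shared = [l for l in pop_div.labels if l in ydist.labels]
    sub_div = pop_div.reorder(shared)
    sub_ident = identical.loc[shared, shared].to_numpy()
    iu = np.triu_indices(len(shared), k=1)
    ident_vec = sub_ident[iu]
    div_vec = sub_div.values[iu]
    frac_identical = float(ident_vec.mean())
    result: dict[str, Any] = {
        "n_pairs": int(len(ident_vec)),
        "fraction_identical_pairs": frac_identical,
    }
    if ident_vec.any() and (~ident_vec).any():
        # shuffle which population carries which yield profile
        rng = np.random.default_rng(seed)
        n = len(shared)
        obs_diff = float(div_vec[~ident_vec].mean())
        obs_same = float(div_vec[ident_vec].mean())
        flip = obs_same > obs_diff
        hi, lo = (obs_same, obs_diff) if flip else (obs_diff, obs_same)
        ratio_obs = hi / lo
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            pident = sub_ident[np.ix_(perm, perm)][iu]
            if not pident.any() or pident.all():
                exceed += 1  # degenerate shuffles cannot beat the observed split
                continue
            m_same = div_vec[pident].mean()
            m_diff = div_vec[~pident].mean()
            num, den = (m_same, m_diff) if flip else (m_diff, m_same)
            if den > 0 and num / den >= ratio_obs - 1e-15:
                exceed += 1
        result["divergence_ratio_different_vs_identical"] = float(obs_diff / obs_same) \
            if obs_same > 0 else np.inf
        result["ratio_observed"] = ratio_obs
        result["p_value"] = (exceed + 1) / (n_permutations + 1)
        result["n_permutations"] = n_permutations
    return result


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Execute the complete comparative analysis described by ``config``.

    Returns the summary dictionary; when ``config.outdir`` is set, also
    writes profiles, distance matrices, signature tables and
    ``summary.json`` there.
    """
    tree, tables, yields, dataset = _load_inputs(config)
    _validate_labels(tree, tables)

    if dataset is not None:
        groups = dataset.truth.groups
        clades = dataset.truth.clades
    else:
        # group labels come from the sample metadata
        any_table = next(iter(tables.values()))
        meta = any_table.meta.loc[~any_table.is_qc]
        groups = meta.drop_duplicates("population").set_index("population")["group"].to_dict()
        clades = None

    summary: dict[str, Any] = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "channels": {},
    }
    artifacts: dict[str, Any] = {}
    for i, channel in enumerate(config.channels):
        if channel not in tables:
            continue
        res = _channel_results(channel, tables[channel], tree, groups, clades,
                               config, rng_seed=config.seed + 1000 * (i + 1))
        artifacts[channel] = {k: res.pop(k) for k in list(res) if k.startswith("_")}
        summary["channels"][channel] = res

    if yields is not None and "targeted" in artifacts:
        summary["yields"] = _yield_results(
            yields, artifacts["targeted"]["_divergence"],
            config.n_permutations, config.seed + 77,
        )

    if dataset is not None and "targeted" in artifacts:
        scan = artifacts["targeted"]["_scan"]
        truth_shift = {t: s for t, s in dataset.truth.shift_traits.items()
                       if t in scan.index}
        detected = set(scan.index[scan["significant"]])
        summary["truth_recovery"] = _recovery_summary(scan, truth_shift, detected)

    if config.outdir:
        _write_bundle(config, summary, artifacts, tree, dataset)
    return summary


def _recovery_summary(scan: pd.DataFrame, truth_shift: Mapping[str, float],
                      detected: set[str]) -> dict[str, Any]:
    planted = set(truth_shift)
    correct_sign = [
        t for t in planted
        if t in detected and np.sign(truth_shift[t]) == scan.loc[t, "sign"]
    ]
    out = {
        "n_planted_shift_traits": len(planted),
        "n_detected": len(detected),
        "n_recovered_correct_sign": len(correct_sign),
    }
    if planted:
        out["sensitivity"] = len(correct_sign) / len(planted)
        universe = set(scan.index)
        odds, p = ps.fisher_exact_overlap(detected, planted, universe)
        out["overlap_odds_ratio"] = odds
        out["overlap_fisher_p"] = p
    return out


def _write_bundle(config: RunConfig, summary: dict, artifacts: dict,
                  tree: Phylogeny, dataset: SimulatedDataset | None) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))
    for channel, art in artifacts.items():
        art["_profiles"].to_csv(outdir / f"{channel}_population_profiles.csv")
        art["_divergence"].to_csv(outdir / f"{channel}_divergence.csv")
        art["_adjusted"].to_csv(outdir / f"{channel}_adjusted_divergence.csv")
        art["_patristic"].to_csv(outdir / f"{channel}_patristic.csv")
        art["_scan"].to_csv(outdir / f"{channel}_signature.csv")
    if dataset is not None:
        dataset.write(outdir / "synthetic_inputs")
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
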