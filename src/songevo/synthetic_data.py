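"""Synthetic trees and trait datasets with the statistical structure the
analyses assume.

The default configuration emulates the shape of the study data: 67
species spread over 24 families on a pure-birth (Yule) tree rescaled to
unit root-to-tip depth; a binary learning-window state evolved under an
Mk process; seven natural-log song traits evolved under state-dependent
Brownian motion whose group offsets echo the observed group means (e.g.
ln syllable repertoire about 1.88 in song-stable and 3.95 in
song-plastic lineages); and binary mating traits whose transition rates
may depend on the learning state along the sampled history.

Every generator is a pure function of (parameters, seed): fixed seeds
give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .mk_ctmc import StateMap, er_generator
from .phylo_core import Phylogeny
from .trait_model import RAW_TRAITS, SpeciesRecord, records_to_csv

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_yule",
    "assign_families",
    "simulate_discrete",
    "simulate_bm_regimes",
    "simulate_dependent_pair",
    "simulate_conditional_binary",
    "generate_study_dataset",
    "write_dataset",
]

#: Group offsets (stable, plastic) on the natural-log scale for each
#: simulated song trait; these echo the observed group means so planted
#: datasets reproduce the repertoire pattern (large repertoire shift,
#: modest or no shift elsewhere).
DEFAULT_OFFSETS = {
    "syllable_repertoire": (1.8807, 3.946),
    "song_repertoire": (1.1055, 3.8688),
    "syllables_per_song": (1.2556, 2.2962),
    "duration_s": (0.7736, 1.2927),
    "interval_s": (1.6075, 1.218),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study dataset.

    Rates are per unit tree depth (trees are rescaled to unit
    root-to-tip depth).  ``learning_rate`` is the symmetric Mk rate of
    the binary learning state; with the default tree shape it yields on
    the order of a dozen state transitions across the tree.  ``sigma2``
    is the Brownian rate shared by all traits and states unless
    overridden per state; ``offsets`` plant group-mean differences.
    """

    n_species: int = 67
    n_families: int = 24
    birth_rate: float = 1.0
    learning_rate: float = 0.7
    sigma2_stable: float = 0.5
    sigma2_plastic: float = 0.5
    offsets: dict = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    p_early: float = 0.35  # fraction of stable species coded early
    n_ternary_missing: int = 8
    n_studies_max: int = 3
    study_noise_sd: float = 0.15  # lognormal spread of per-study values
    # mating-trait gain/loss rates conditional on the learning state
    mating_rates_stable: tuple = (0.3, 0.3)
    mating_rates_plastic: tuple = (3.0, 3.0)
    epp_rates: tuple = (0.5, 0.5)  # state-independent
    missing: dict = field(
        default_factory=lambda: {
            "song_repertoire": 5,
            "syllables_per_song": 12,
            "duration_s": 22,
            "interval_s": 22,
            "mating": 10,
            "epp": 26,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_families > self.n_species:
            raise ValueError("n_families must be <= n_species")
        for name in ("birth_rate", "learning_rate", "sigma2_stable", "sigma2_plastic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SyntheticDataset:
    tree: Phylogeny
    records: list
    families: dict
    true_learning: dict
    true_map: StateMap
    true_log_traits: dict  # trait -> {species: ln value}
    metadata: dict


def _subseed(master: int | None, *key: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return np.random.default_rng(ss)


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------

def simulate_yule(
    n_tips: int, seed: int | None = 0, birth_rate: float = 1.0
) -> Phylogeny:
    """Pure-birth tree with ``n_tips``, rescaled to unit root-to-tip depth.

    Standard forward construction: starting from the root's two
    daughters, each extant lineage splits at rate ``birth_rate``; after
    the (n-1)-th split the process runs one more exponential waiting
    time and all extant lineages are cut there, giving an ultrametric
    tree.  Tips are labeled ``sp01 .. spNN`` in tree order.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = _subseed(seed, 0)
    parent: dict[int, int] = {}
    children: dict[int, list[int]] = {0: [1, 2], 1: [], 2: []}
    birth = {0: 0.0, 1: 0.0, 2: 0.0}  # time the lineage began
    active = [1, 2]
    next_id = 3
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = active[rng.integers(len(active))]
        c1, c2 = next_id, next_id + 1
        next_id += 2
        children[i] = [c1, c2]
        children[c1] = []
        children[c2] = []
        parent[c1] = i
        parent[c2] = i
        birth[c1] = birth[c2] = t
        active.remove(i)
        active.extend([c1, c2])
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    for i in (1, 2):
        parent[i] = 0
    branch_length = {}
    death = {n: (birth[children[n][0]] if children[n] else t_end) for n in children}
    for n in children:
        if n != 0:
            branch_length[n] = (death[n] - birth[n]) / t_end
    labels = {}
    k = 0
    tree = Phylogeny(parent, children, branch_length, labels, root=0)
    width = max(2, len(str(n_tips)))
    for node in tree.postorder():
        if not children[node]:
            k += 1
            labels[node] = f"sp{k:0{width}d}"
    tree.validate()
    return tree


def assign_families(
    tree: Phylogeny, n_families: int, prefix: str = "fam"
) -> dict[str, str]:
    """Family labels by cutting the tree at the shallowest depth with at
    least ``n_families`` crossing lineages; each tip inherits the family
    of its crossing ancestor edge."""
    depth = tree.depths()
    split_depths = sorted(
        depth[n] for n in tree.nodes if tree.children[n]
    )
    if n_families > len(split_depths) + 1:
        raise ValueError("not enough splits for the requested family count")
    if n_families <= 1:
        return {lab: f"{prefix}01" for lab in tree.tip_labels}
    d_m = split_depths[n_families - 2]
    later = [d for d in split_depths if d > d_m]
    cut = 0.5 * (d_m + (later[0] if later else d_m + (1.0 - d_m))) + 1e-12
    clades = [
        n
        for n in tree.nodes
        if n != tree.root and depth[tree.parent[n]] < cut <= depth[n]
    ] + [
        n
        for n in tree.nodes
        if tree.children[n] == [] and depth[n] < cut
    ]
    clades.sort()
    width = max(2, len(str(len(clades))))
    fam_of_node = {n: f"{prefix}{i + 1:0{width}d}" for i, n in enumerate(clades)}
    out: dict[str, str] = {}
    for tip in tree.tips:
        node = tip
        while node not in fam_of_node:
            node = tree.parent[node]
        out[tree.labels[tip]] = fam_of_node[node]
    return out


# ----------------------------------------------------------------------
# discrete characters
# ----------------------------------------------------------------------

def simulate_discrete(
    tree: Phylogeny,
    Q: np.ndarray,
    states: Sequence,
    root_state,
    seed: int | None = 0,
) -> tuple[dict[str, object], StateMap]:
    """Exact branch-by-branch CTMC simulation (Gillespie).

    Returns observed tip states and the full true history as a
    :class:`StateMap` satisfying the map invariants.
    """
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    idx = {s: i for i, s in enumerate(states)}
    rng = _subseed(seed, 1)
    node_state = {tree.root: idx[root_state]}
    segments: dict[int, list[tuple[int, float]]] = {}
    for node in tree.preorder():
        if node == tree.root:
            continue
        s = node_state[tree.parent[node]]
        t_total = tree.branch_length[node]
        segs: list[tuple[int, float]] = []
        t_used = 0.0
        cur_start = 0.0
        while True:
            rate = -Q[s, s]
            wait = rng.exponential(1.0 / rate) if rate > 0 else math.inf
            if t_used + wait >= t_total:
                segs.append((s, t_total - cur_start))
                break
            t_used += wait
            probs = Q[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            s_new = int(rng.choice(k, p=probs))
            segs.append((s, t_used - cur_start))
            cur_start = t_used
            s = s_new
        node_state[node] = s
        segments[node] = segs
    tip_states = {
        tree.labels[t]: states[node_state[t]] for t in tree.tips
    }
    smap = StateMap(
        states=tuple(states),
        segments=segments,
        node_states=node_state,
    )
    return tip_states, smap


def simulate_dependent_pair(
    tree: Phylogeny,
    rates8: Sequence[float],
    root_state: tuple = (0, 0),
    seed: int | None = 0,
) -> tuple[dict[str, tuple], StateMap]:
    """Paired binary traits evolved under a dependent 4-state CTMC.

    Dual transitions are structural zeros of the generator, so no
    simulated path ever changes both traits at once.
    """
    from .pagel_sweep import PAIR_STATES, dependent_generator

    Q = dependent_generator(rates8)
    return simulate_discrete(tree, Q, PAIR_STATES, tuple(root_state), seed=seed)


def simulate_conditional_binary(
    tree: Phylogeny,
    state_map: StateMap,
    gain_loss_by_state: Mapping[object, tuple],
    root_state: int = 0,
    seed: int | None = 0,
) -> dict[str, int]:
    """A binary trait whose gain/loss rates switch with a painted state.

    Together with the painted character this realizes a dependent
    4-state chain in which the painted trait's own rates do not depend
    on the binary trait (the other four dependencies are free).  Used to
    plant correlated evolution of mating traits on a learning history.
    """
    rng = _subseed(seed, 2)
    node_val = {tree.root: int(root_state)}
    for node in tree.preorder():
        if node == tree.root:
            continue
        v = node_val[tree.parent[node]]
        for s_idx, dur in state_map.segments[node]:
            painted = state_map.states[s_idx]
            gain, loss = gain_loss_by_state[painted]
            t_used = 0.0
            while True:
                rate = loss if v == 1 else gain
                wait = rng.exponential(1.0 / rate) if rate > 0 else math.inf
                if t_used + wait >= dur:
                    break
                t_used += wait
                v = 1 - v
        node_val[node] = v
    return {tree.labels[t]: node_val[t] for t in tree.tips}


# ----------------------------------------------------------------------
# continuous characters
# ----------------------------------------------------------------------

def simulate_bm_regimes(
    tree: Phylogeny,
    state_map: StateMap,
    sigma2_by_state: Mapping[object, float],
    state_offsets: Mapping[object, float] | None = None,
    root_value: float = 0.0,
    seed: int | None = 0,
) -> dict[str, float]:
    """Brownian motion with per-state rates along a painted history.

    Each branch segment contributes a Gaussian increment with variance
    ``sigma2(state) * duration``; an optional additive state offset is
    applied at the tips to plant group-mean differences.
    """
    rng = _subseed(seed, 3)
    node_val = {tree.root: float(root_value)}
    for node in tree.preorder():
        if node == tree.root:
            continue
        v = node_val[tree.parent[node]]
        for s_idx, dur in state_map.segments[node]:
            s2 = float(sigma2_by_state[state_map.states[s_idx]])
            if dur > 0:
                v += rng.normal(0.0, math.sqrt(s2 * dur))
        node_val[node] = v
    out = {}
    for t in tree.tips:
        v = node_val[t]
        if state_offsets is not None:
            tip_state = state_map.states[state_map.node_states[t]]
            v += float(state_offsets[tip_state])
        out[tree.labels[t]] = v
    return out


# ----------------------------------------------------------------------
# full study dataset
# ----------------------------------------------------------------------

def generate_study_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """One synthetic study: tree, families, codings, traits, mating.

    The learning window is simulated as a binary Mk character; ternary
    codings subdivide stable species into early/delayed independently of
    phylogeny; continuous years are drawn uniform [0.5, 1] for early
    species, fixed 1.33 for delayed and 2.0 for plastic.  Song traits
    are state-dependent BM on the true learning history with group
    offsets; per-study raw values jitter the true value lognormally so
    the aggregation modes differ.  Mating traits evolve conditionally on
    the learning history (state-dependent switch rates); missingness is
    planted by random removal.
    """
    config.validate()
    seed = config.seed
    tree = simulate_yule(config.n_species, seed=seed, birth_rate=config.birth_rate)
    families = assign_families(tree, config.n_families)
    states = ("stable", "plastic")
    Q = er_generator(2, config.learning_rate)
    learn, smap = simulate_discrete(tree, Q, states, "stable", seed=seed)

    sigma2 = {"stable": config.sigma2_stable, "plastic": config.sigma2_plastic}
    true_logs: dict[str, dict[str, float]] = {}
    for j, trait in enumerate(RAW_TRAITS):
        off_s, off_p = config.offsets[trait]
        true_logs[trait] = simulate_bm_regimes(
            tree,
            smap,
            sigma2,
            {"stable": off_s, "plastic": off_p},
            root_value=0.0,
            seed=None if seed is None else seed * 1000 + 10 + j,
        )

    mating01 = simulate_conditional_binary(
        tree,
        smap,
        {
            "stable": config.mating_rates_stable,
            "plastic": config.mating_rates_plastic,
        },
        seed=None if seed is None else seed * 1000 + 20,
    )
    epp01 = simulate_conditional_binary(
        tree,
        smap,
        {"stable": config.epp_rates, "plastic": config.epp_rates},
        seed=None if seed is None else seed * 1000 + 21,
    )

    rng = _subseed(seed, 4)
    species = tree.tip_labels
    stable_sp = [s for s in species if learn[s] == "stable"]
    early_set = {s for s in stable_sp if rng.uniform() < config.p_early}
    ternary_missing = set(
        rng.choice(species, size=min(config.n_ternary_missing, len(species)), replace=False)
    )
    miss = dict(config.missing)
    miss_sets: dict[str, set] = {}
    for key in ("song_repertoire", "syllables_per_song", "mating", "epp"):
        n_miss = min(miss.get(key, 0), len(species) - 3)
        miss_sets[key] = set(rng.choice(species, size=n_miss, replace=False))
    n_miss_di = min(miss.get("duration_s", 0), len(species) - 3)
    di_missing = set(rng.choice(species, size=n_miss_di, replace=False))
    miss_sets["duration_s"] = di_missing
    miss_sets["interval_s"] = di_missing  # duration and interval co-occur
    miss_sets["syllable_repertoire"] = set()

    records: list[SpeciesRecord] = []
    for s in species:
        binary = learn[s]
        if s in ternary_missing:
            ternary = None
            years = None
        elif binary == "plastic":
            ternary = "plastic"
            years = 2.0
        elif s in early_set:
            ternary = "early"
            years = float(np.round(rng.uniform(0.5, 1.0), 3))
        else:
            ternary = "delayed"
            years = 1.33
        kwargs: dict[str, object] = {
            "species": s,
            "family": families[s],
            "learning_binary": binary,
            "learning_ternary": ternary,
            "learning_years": years,
        }
        for trait in RAW_TRAITS:
            if s in miss_sets[trait]:
                kwargs[trait] = []
                continue
            n_st = int(rng.integers(1, config.n_studies_max + 1))
            true_raw = math.exp(true_logs[trait][s])
            vals = [
                float(true_raw * math.exp(rng.normal(0.0, config.study_noise_sd)))
                for _ in range(n_st)
            ]
            kwargs[trait] = vals
        if s in miss_sets["mating"]:
            kwargs["polygynous_male_fraction"] = None
        else:
            kwargs["polygynous_male_fraction"] = 0.2 if mating01[s] == 1 else 0.01
        if s in miss_sets["epp"]:
            kwargs["epp_fraction"] = None
        else:
            kwargs["epp_fraction"] = 0.25 if epp01[s] == 1 else 0.03
        rec = SpeciesRecord(**kwargs)
        rec.validate()
        records.append(rec)

    meta = {
        "config": _config_dict(config),
        "seed": seed,
        "n_species": config.n_species,
        "n_families": len(set(families.values())),
        "n_stable": len(stable_sp),
        "n_plastic": len(species) - len(stable_sp),
    }
    return SyntheticDataset(
        tree=tree,
        records=records,
        families=families,
        true_learning=learn,
        true_map=smap,
        true_log_traits=true_logs,
        metadata=meta,
    )


def _config_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["offsets"] = {k: list(v) for k, v in d["offsets"].items()}
    return d


def write_dataset(config: SyntheticConfig, outdir: str | Path) -> dict:
    """Materialize a synthetic study as Newick + trait CSV + metadata JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds = generate_study_dataset(config)
    newick = ds.tree.to_newick()
    (out / "tree.nwk").write_text(newick + "\n")
    records_to_csv(ds.records, str(out / "traits.csv"))
    payload = dict(ds.metadata)
    digest = hashlib.sha256(
        (newick + (out / "traits.csv").read_text()).encode()
    ).hexdigest()
    payload["content_sha256"] = digest
    (out / "metadata.json").write_text(json.dumps(payload, indent=2) + "\n")
    return {
        "tree": str(out / "tree.nwk"),
        "traits": str(out / "traits.csv"),
        "metadata": str(out / "metadata.json"),
        "content_sha256": digest,
    }
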