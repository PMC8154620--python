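"""End-to-end coil-globule analysis pipeline.

Stages, composed over all temperatures and replicas:

1. ingest or generate bead-chain trajectories;
2. per-frame descriptors (Rg, sigma, Omega, nu) and backbone torsions;
3. global discretization (standard scaling + k-means, shared across
   temperatures);
4. macrostate assignment: a quantile prescreen on (Rg, sigma) labels
   clear coils and globules, and a per-temperature two-hidden-state HMM
   resolves the remaining ambiguous frames by the dynamics;
5. thermodynamics (K_eq, dG, van't Hoff), kinetics (MFPT rates, Eyring)
   and torsional entropy (dS_pol), each with replica leave-one-out
   spreads;
6. per-temperature substate HMMs in the shared cluster space, matched
   across temperatures into a named catalog (C0, C1, ... by descending
   Rg within the coil; G0, G1, ... by ascending Rg within the globule).

Every stage draws randomness from the config seed; re-running with the
same config reproduces byte-identical CSV/JSON artifacts.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import descriptors as desc
from . import entropy as ent
from . import hmm as hmm_mod
from . import io as io_mod
from . import msm as msm_mod
from . import thermo as thermo_mod
from .synthetic import make_cgt_study

logger = logging.getLogger("cgtkit.pipeline")

__all__ = [
    "prescreen_macrostates",
    "quantile_thresholds",
    "resolve_ambiguous",
    "choose_n_substates",
    "build_substate_models",
    "SubstateCatalog",
    "match_substates",
    "occupancy_table",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Macrostate assignment
# ---------------------------------------------------------------------------

def quantile_thresholds(
    descriptors_df: pd.DataFrame,
    rg_low_q: float = 0.35,
    rg_high_q: float = 0.65,
    sasa_low_q: float = 0.50,
) -> tuple[float, float, float]:
    """Prescreen thresholds from pooled descriptor quantiles."""
    rg = descriptors_df["rg_nm"].to_numpy()
    sg = descriptors_df["sasa_nm2"].to_numpy()
    return (
        float(np.quantile(rg, rg_low_q)),
        float(np.quantile(rg, rg_high_q)),
        float(np.quantile(sg, sasa_low_q)),
    )


def prescreen_macrostates(
    descriptors_df: pd.DataFrame,
    rg_low: float,
    rg_high: float,
    sasa_low: float,
) -> np.ndarray:
    """Label frames coil / globule / ambiguous from (Rg, sigma) thresholds.

    Globule: Rg < rg_low and sigma < sasa_low.  Coil: Rg > rg_high.
    Everything else is ambiguous and left to the hidden Markov model.
    """
    if not rg_low < rg_high:
        raise ValueError("thresholds must satisfy rg_low < rg_high")
    rg = descriptors_df["rg_nm"].to_numpy()
    sg = descriptors_df["sasa_nm2"].to_numpy()
    labels = np.full(rg.size, "ambiguous", dtype=object)
    labels[(rg < rg_low) & (sg < sasa_low)] = "globule"
    labels[rg > rg_high] = "coil"
    return labels


def resolve_ambiguous(
    prescreen_labels: np.ndarray,
    hidden_path: np.ndarray,
    agreement_warn: float = 0.60,
) -> tuple[np.ndarray, dict[int, str]]:
    """Final macrostate per frame: prescreen where clear, HMM where not.

    The hidden-state -> macrostate map is the one maximising agreement
    with the unambiguous prescreen labels (per-state majority vote,
    which is invariant to hidden-state relabelling).  Returns the final
    labels and the map; warns when overall agreement falls below
    ``agreement_warn``.
    """
    labels = np.asarray(prescreen_labels, dtype=object)
    path = np.asarray(hidden_path, dtype=int)
    if labels.shape != path.shape:
        raise ValueError("prescreen labels and hidden path must align per frame")
    clear = labels != "ambiguous"
    macro_map: dict[int, str] = {}
    for h in np.unique(path):
        sel = clear & (path == h)
        if sel.sum() == 0:
            macro_map[h] = "coil"  # no evidence; arbitrary but deterministic
            continue
        n_coil = int((labels[sel] == "coil").sum())
        n_glob = int((labels[sel] == "globule").sum())
        macro_map[h] = "coil" if n_coil >= n_glob else "globule"
    mapped = np.array([macro_map[h] for h in path], dtype=object)
    agree = float((mapped[clear] == labels[clear]).mean()) if clear.any() else 1.0
    if agree < agreement_warn:
        warnings.warn(
            f"hidden-state map agrees with only {agree:.1%} of unambiguous "
            "frames; model and prescreen disagree",
            stacklevel=2,
        )
    final = labels.copy()
    final[~clear] = mapped[~clear]
    return final, macro_map


# ---------------------------------------------------------------------------
# Substates
# ---------------------------------------------------------------------------

def choose_n_substates(
    model: msm_mod.MarkovModel, max_states: int = 7, n_timescales: int = 10
) -> int:
    """Number of substates from the largest relative implied-timescale gap.

    With timescales t_1 >= t_2 >= ..., a gap after t_m suggests m + 1
    metastable sets (the stationary process contributes one more).
    Capped at ``max_states``.
    """
    ts = msm_mod.implied_timescales(model, n_timescales)
    ts = ts[np.isfinite(ts) & (ts > 0)]
    if ts.size < 2:
        return 2
    ratios = ts[:-1] / ts[1:]
    m = int(np.argmax(ratios)) + 1
    return int(np.clip(m + 1, 2, max_states))


def build_substate_models(
    discrete_trajs: dict[tuple[float, int], np.ndarray],
    descriptors_df: pd.DataFrame,
    disc: msm_mod.Discretization,
    macro_labels: np.ndarray,
    lags: dict[float, int],
    n_hidden: dict[float, int],
    seed: int = 0,
    frame_spacing: float = 1.0,
) -> dict[float, dict]:
    """Per-temperature substate HMMs plus descriptor-space state positions.

    Each hidden state's 4D position is the mean scaled descriptor of its
    Viterbi-assigned frames; its occupancy is the stationary probability
    of the hidden chain; its macrostate is the majority macrostate of
    its frames.  The discretization must be the global (shared) one.
    """
    X_scaled = disc.transform(
        descriptors_df[msm_mod.DESCRIPTOR_COLUMNS].to_numpy(dtype=float)
    )
    temps = sorted({T for (T, _r) in discrete_trajs})
    key = descriptors_df[["temperature", "replica", "frame"]]
    out: dict[float, dict] = {}
    for ti, T in enumerate(temps):
        trajs = [discrete_trajs[k] for k in sorted(discrete_trajs) if k[0] == T]
        lag = lags[T]
        k_hidden = n_hidden[T]
        micro = msm_mod.estimate_transition_matrix(
            msm_mod.count_transitions(trajs, lag, disc.n_centers), lag
        )
        groups_active = hmm_mod.spectral_initial_groups(
            micro.transition_matrix, k_hidden, seed=seed + ti
        )
        groups = np.zeros(disc.n_centers, dtype=int)
        groups[micro.active_set] = groups_active
        B0 = hmm_mod.initial_emissions_from_groups(groups, trajs, disc.n_centers)
        model = hmm_mod.baum_welch(
            trajs,
            n_hidden=k_hidden,
            lag=lag,
            n_symbols=disc.n_centers,
            init_emissions=B0,
            seed=seed + ti,
            frame_spacing=frame_spacing,
        )
        # per-frame hidden labels at this temperature, in frame order
        sel_rows = []
        paths = []
        for k in sorted(discrete_trajs):
            if k[0] != T:
                continue
            idx = np.flatnonzero(
                (key["temperature"].to_numpy() == k[0])
                & (key["replica"].to_numpy() == k[1])
            )
            idx = idx[np.argsort(key["frame"].to_numpy()[idx])]
            sel_rows.append(idx)
            paths.append(hmm_mod.viterbi_assign(model, discrete_trajs[k]))
        rows = np.concatenate(sel_rows)
        path = np.concatenate(paths)
        positions, occupancy, macro_of = {}, {}, {}
        stat = model.stationary
        for h in range(k_hidden):
            sel = path == h
            if sel.sum() == 0:
                continue
            positions[h] = X_scaled[rows[sel]].mean(axis=0)
            occupancy[h] = float(stat[h])
            mlabels = macro_labels[rows[sel]]
            n_coil = int((mlabels == "coil").sum())
            macro_of[h] = "coil" if n_coil >= sel.sum() - n_coil else "globule"
        tot = sum(occupancy.values())
        occupancy = {h: p / tot for h, p in occupancy.items()}
        out[T] = {
            "model": model,
            "positions": positions,
            "occupancy": occupancy,
            "macrostate": macro_of,
            "hidden_path_rows": (rows, path),
        }
    return out


@dataclass
class SubstateCatalog:
    """Named substates matched across temperatures.

    ``reference_positions`` maps name -> mean scaled 4D coordinates,
    ``occupancy`` maps temperature -> {name: stationary probability},
    ``membership`` maps temperature -> {hidden-state index: name}.
    """

    reference_positions: dict[str, np.ndarray]
    macrostate: dict[str, str]
    occupancy: dict[float, dict[str, float]]
    membership: dict[float, dict[int, str]]
    unmatched_flags: list[str] = field(default_factory=list)


def match_substates(
    substates: dict[float, dict],
    disc: msm_mod.Discretization,
    r_match: float = 1.0,
) -> SubstateCatalog:
    """Greedy agglomerative matching of substate positions across temperatures.

    Temperatures are processed in sorted order (so the catalog does not
    depend on input ordering); within a temperature, states join the
    nearest same-macrostate reference within ``r_match`` (scaled
    Euclidean distance), one state per reference, largest occupancy
    first.  Unmatched states open a new reference; references track the
    running mean of their members.  Names follow the Rg-rank convention:
    C0 is the coil with the largest Rg, G0 the globule with the smallest.
    """
    refs: list[dict] = []  # {"pos", "macro", "n", "members": {T: h}}
    for T in sorted(substates):
        entry = substates[T]
        order = sorted(
            entry["positions"], key=lambda h: -entry["occupancy"].get(h, 0.0)
        )
        claimed: set[int] = set()
        for h in order:
            pos = entry["positions"][h]
            macro = entry["macrostate"][h]
            best, best_d = None, np.inf
            for ri, ref in enumerate(refs):
                if ri in claimed or ref["macro"] != macro:
                    continue
                d = float(np.linalg.norm(ref["pos"] - pos))
                if d < best_d:
                    best, best_d = ri, d
            if best is not None and best_d < r_match:
                ref = refs[best]
                ref["pos"] = (ref["pos"] * ref["n"] + pos) / (ref["n"] + 1)
                ref["n"] += 1
                ref["members"][T] = h
                claimed.add(best)
            else:
                refs.append({"pos": pos.copy(), "macro": macro, "n": 1,
                             "members": {T: h}})
                claimed.add(len(refs) - 1)

    # name by macrostate + Rg rank (descriptor dim 0 is Rg; unscale it)
    def ref_rg(ref):
        return ref["pos"][0] * disc.scale[0] + disc.mean[0]

    names: dict[int, str] = {}
    coils = sorted(
        (i for i, r in enumerate(refs) if r["macro"] == "coil"),
        key=lambda i: -ref_rg(refs[i]),
    )
    globs = sorted(
        (i for i, r in enumerate(refs) if r["macro"] == "globule"),
        key=lambda i: ref_rg(refs[i]),
    )
    for rank, i in enumerate(coils):
        names[i] = f"C{rank}"
    for rank, i in enumerate(globs):
        names[i] = f"G{rank}"

    n_temps = len(substates)
    unmatched = [
        names[i] for i, r in enumerate(refs) if len(r["members"]) < n_temps
    ]
    occupancy: dict[float, dict[str, float]] = {}
    membership: dict[float, dict[int, str]] = {}
    for T in sorted(substates):
        occupancy[T] = {}
        membership[T] = {}
        for i, ref in enumerate(refs):
            if T in ref["members"]:
                h = ref["members"][T]
                occupancy[T][names[i]] = substates[T]["occupancy"][h]
                membership[T][h] = names[i]
    return SubstateCatalog(
        reference_positions={names[i]: r["pos"] for i, r in enumerate(refs)},
        macrostate={names[i]: r["macro"] for i, r in enumerate(refs)},
        occupancy=occupancy,
        membership=membership,
        unmatched_flags=sorted(unmatched),
    )


def occupancy_table(catalog: SubstateCatalog) -> pd.DataFrame:
    """Tidy (temperature, substate, occupancy) table; absent states get 0."""
    all_names = sorted(catalog.reference_positions)
    rows = []
    for T in sorted(catalog.occupancy):
        occ = catalog.occupancy[T]
        for name in all_names:
            rows.append(
                {"temperature": T, "substate": name, "occupancy": occ.get(name, 0.0)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis, with study-scale defaults."""

    # synthetic study (used when no trajectories are supplied)
    temperatures: tuple = (277.0, 280.0, 283.0, 286.0, 289.0, 292.0)
    n_replicas: int = 4
    n_frames: int = 20_000
    dH: float = 100.0  # kJ/mol
    dS: float = 351.86  # J/(mol K)
    noise_sd: float = 0.03  # nm
    n_beads: int = 20
    seed: int = 0
    # descriptors
    segment_length: int = 3
    contact_cutoff: float = 0.8  # nm
    bead_radius: float = 0.25  # nm
    probe_radius: float = 0.14  # nm
    n_sphere_points: int = 144  # SASA quadrature for bulk trajectories
    # discretization / models
    n_clusters: int = 250
    lag: int | str = 1  # frames, or "auto" for the timescale-plateau rule
    n_hidden_substates: int | str = 4  # or "auto" for the timescale-gap rule
    # macrostate prescreen quantiles
    rg_low_q: float = 0.35
    rg_high_q: float = 0.65
    sasa_low_q: float = 0.50
    # thermo / entropy
    pseudocount: bool = False
    entropy_grid: int = 360
    entropy_min_frames: int = 1000
    fep_bin_width: float = 0.01  # nm, Rg free-energy profile
    fep_min_count: int = 10
    # substate matching
    r_match: float = 1.0
    # output
    out_dir: str | None = None
    write_frame_tables: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, val in data.items():
            if isinstance(val, dict):  # nested sections are flattened
                flat.update(val)
            else:
                flat[key] = val
        if "temperatures" in flat:
            flat["temperatures"] = tuple(float(t) for t in flat["temperatures"])
        return cls(**flat)


@dataclass
class PipelineResult:
    """Everything the pipeline computes, in memory."""

    config: PipelineConfig
    descriptors: pd.DataFrame
    dihedrals: pd.DataFrame
    discretization: msm_mod.Discretization
    macro_labels: np.ndarray
    macro_models: dict
    K_eq: dict[float, float]
    dG: dict[float, float]
    vant_hoff: thermo_mod.VantHoffFit
    rates: dict[float, tuple[float, float]]
    eyring_forward: thermo_mod.EyringFit | None
    eyring_backward: thermo_mod.EyringFit | None
    entropy: dict[float, ent.EntropyResult]
    profiles: dict[float, thermo_mod.FreeEnergyProfile]
    catalog: SubstateCatalog
    occupancies: pd.DataFrame
    ground_truth: object | None = None
    artifacts: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    trajectories: list | None = None,
    ground_truth=None,
) -> PipelineResult:
    """Run all stages; generate the synthetic study when no data is given.

    When ``config.out_dir`` is set, results are written as CSV/JSON with
    a manifest; re-running with the same config yields byte-identical
    artifacts.
    """
    t0 = time.time()
    stages: dict[str, str] = {}

    def _stage(name: str):
        stages[name] = "ok"
        logger.info("stage %-14s done at %.1fs", name, time.time() - t0)

    if trajectories is None:
        study = make_cgt_study(
            temperatures=np.asarray(config.temperatures),
            n_replicas=config.n_replicas,
            n_frames=config.n_frames,
            dH=config.dH,
            dS=config.dS,
            noise_sd=config.noise_sd,
            n_beads=config.n_beads,
            seed=config.seed,
        )
        trajectories = study.trajectories
        ground_truth = study.ground_truth
    _stage("data")

    dcfg = desc.DescriptorConfig(
        segment_length=config.segment_length,
        contact_cutoff=config.contact_cutoff,
        bead_radius=config.bead_radius,
        probe_radius=config.probe_radius,
        n_sphere_points=config.n_sphere_points,
    )
    ddf = pd.concat(
        [desc.descriptor_series(t, dcfg) for t in trajectories], ignore_index=True
    )
    phidf = pd.concat(
        [desc.dihedral_series(t) for t in trajectories], ignore_index=True
    )
    frame_spacing = trajectories[0].frame_spacing
    _stage("descriptors")

    disc = msm_mod.fit_discretization(ddf, config.n_clusters, seed=config.seed)
    cluster_labels = msm_mod.assign(disc, ddf)
    discrete = msm_mod.split_discrete_trajectories(ddf, cluster_labels)
    _stage("discretize")

    temps = sorted({k[0] for k in discrete})
    lags: dict[float, int] = {}
    for T in temps:
        trajs_T = [discrete[k] for k in sorted(discrete) if k[0] == T]
        if config.lag == "auto":
            lags[T] = msm_mod.recommend_lag(trajs_T)
        else:
            lags[T] = int(config.lag)

    rg_low, rg_high, sasa_low = quantile_thresholds(
        ddf, config.rg_low_q, config.rg_high_q, config.sasa_low_q
    )
    pres = prescreen_macrostates(ddf, rg_low, rg_high, sasa_low)

    macro_labels = np.empty(len(ddf), dtype=object)
    macro_models: dict[float, dict] = {}
    K_eq: dict[float, float] = {}
    dG: dict[float, float] = {}
    rates: dict[float, tuple[float, float]] = {}
    key_T = ddf["temperature"].to_numpy()
    key_R = ddf["replica"].to_numpy()
    key_F = ddf["frame"].to_numpy()
    for ti, T in enumerate(temps):
        trajs_T, row_blocks = [], []
        for k in sorted(discrete):
            if k[0] != T:
                continue
            idx = np.flatnonzero((key_T == k[0]) & (key_R == k[1]))
            idx = idx[np.argsort(key_F[idx])]
            trajs_T.append(discrete[k])
            row_blocks.append(idx)
        lag = lags[T]
        micro = msm_mod.estimate_transition_matrix(
            msm_mod.count_transitions(trajs_T, lag, disc.n_centers), lag
        )
        groups_active = msm_mod.pcca_two_state(micro)
        groups = np.zeros(disc.n_centers, dtype=int)
        groups[micro.active_set] = groups_active
        B0 = hmm_mod.initial_emissions_from_groups(groups, trajs_T, disc.n_centers)
        # emissions stay pinned to the PCCA cluster split: the two hidden
        # states must mean "coil" and "globule", and only the exchange
        # kinetics between them are re-estimated by EM
        model2 = hmm_mod.baum_welch(
            trajs_T,
            n_hidden=2,
            lag=lag,
            n_symbols=disc.n_centers,
            init_emissions=B0,
            seed=config.seed + 1000 + ti,
            frame_spacing=frame_spacing,
            update_emissions=False,
        )
        paths = [hmm_mod.viterbi_assign(model2, t) for t in trajs_T]
        rows = np.concatenate(row_blocks)
        path = np.concatenate(paths)
        final_T, macro_map = resolve_ambiguous(pres[rows], path)
        macro_labels[rows] = final_T
        model2.macrostate_map = macro_map
        macro_models[T] = {
            "model": model2,
            "lag": lag,
            "rows": rows,
            "macro_map": macro_map,
        }
        K = thermo_mod.equilibrium_constant(final_T, pseudocount=config.pseudocount)
        K_eq[T] = K
        dG[T] = thermo_mod.free_energy(K, T)
        # kinetics from the resolved macrostate process itself: a 2-state
        # Markov model on the per-replica coil/globule sequences is robust
        # to how the hidden states partition substates internally
        offsets = np.cumsum([0] + [len(t) for t in trajs_T])
        macro_seqs = [
            (final_T[offsets[i] : offsets[i + 1]] == "globule").astype(int)
            for i in range(len(trajs_T))
        ]
        macro_msm = msm_mod.estimate_transition_matrix(
            msm_mod.count_transitions(macro_seqs, lag, 2), lag
        )
        rates[T] = thermo_mod.rates_from_mfpt(
            macro_msm.transition_matrix,
            np.array(["coil", "globule"])[macro_msm.active_set],
            lag=lag,
            frame_spacing=frame_spacing,
            stationary=macro_msm.stationary,
        )
    _stage("macrostates")

    temps_arr = np.array(temps)
    vh = thermo_mod.vant_hoff_fit(temps_arr, np.array([K_eq[T] for T in temps]))

    replicas = sorted({k[1] for k in discrete})
    if len(replicas) >= 3:

        def _vh_stat(stat):
            def estimator(keep_reps):
                keep = np.isin(key_R, keep_reps)
                Ks = []
                for T in temps:
                    sel = keep & (key_T == T)
                    Ks.append(
                        thermo_mod.equilibrium_constant(
                            macro_labels[sel], pseudocount=config.pseudocount
                        )
                    )
                f = thermo_mod.vant_hoff_fit(temps_arr, np.array(Ks))
                return getattr(f, stat)

            return estimator

        vh.loo_spread = {
            stat: thermo_mod.loo_cross_validate(replicas, _vh_stat(stat))
            for stat in ("dH", "dS", "T_star")
        }

    profiles: dict[float, thermo_mod.FreeEnergyProfile] = {}
    rg_all = ddf["rg_nm"].to_numpy()
    for T in temps:
        try:
            profiles[T] = thermo_mod.free_energy_profile(
                rg_all[key_T == T], T, config.fep_bin_width, config.fep_min_count
            )
        except ValueError as err:
            warnings.warn(f"no free-energy profile at T={T:g}: {err}", stacklevel=2)

    k_fwd = np.array([rates[T][0] for T in temps])
    k_bwd = np.array([rates[T][1] for T in temps])
    try:
        ey_f = thermo_mod.eyring_fit(temps_arr, k_fwd)
        ey_b = thermo_mod.eyring_fit(temps_arr, k_bwd)
    except ValueError:
        ey_f = ey_b = None
    _stage("thermo_kinetics")

    entropy_results: dict[float, ent.EntropyResult] = {}
    phi_T = phidf["temperature"].to_numpy()
    for T in temps:
        selT = phi_T == T
        coil_mask = selT & (macro_labels == "coil")
        glob_mask = selT & (macro_labels == "globule")
        entropy_results[T] = ent.delta_entropy(
            phidf,
            coil_mask,
            glob_mask,
            grid_size=config.entropy_grid,
            min_frames=config.entropy_min_frames,
        )
    _stage("entropy")

    n_hidden: dict[float, int] = {}
    for T in temps:
        if config.n_hidden_substates == "auto":
            trajs_T = [discrete[k] for k in sorted(discrete) if k[0] == T]
            micro = msm_mod.estimate_transition_matrix(
                msm_mod.count_transitions(trajs_T, lags[T], disc.n_centers), lags[T]
            )
            n_hidden[T] = choose_n_substates(micro)
        else:
            n_hidden[T] = int(config.n_hidden_substates)
    substates = build_substate_models(
        discrete, ddf, disc, macro_labels, lags, n_hidden,
        seed=config.seed + 2000, frame_spacing=frame_spacing,
    )
    catalog = match_substates(substates, disc, config.r_match)
    occ = occupancy_table(catalog)
    _stage("substates")

    result = PipelineResult(
        config=config,
        descriptors=ddf,
        dihedrals=phidf,
        discretization=disc,
        macro_labels=macro_labels,
        macro_models=macro_models,
        K_eq=K_eq,
        dG=dG,
        vant_hoff=vh,
        rates=rates,
        eyring_forward=ey_f,
        eyring_backward=ey_b,
        entropy=entropy_results,
        profiles=profiles,
        catalog=catalog,
        occupancies=occ,
        ground_truth=ground_truth,
    )
    if config.out_dir is not None:
        result.artifacts = _write_artifacts(result)
        _stage("write")
    return result


def _write_artifacts(result: PipelineResult) -> dict:
    config = result.config
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    temps = sorted(result.K_eq)
    thermo_json = {
        "K_eq": {f"{T:g}": result.K_eq[T] for T in temps},
        "dG_kJ_mol": {f"{T:g}": result.dG[T] for T in temps},
        "dH_kJ_mol": result.vant_hoff.dH,
        "dS_J_mol_K": result.vant_hoff.dS,
        "T_star_K": result.vant_hoff.T_star,
        "r_squared_linear": result.vant_hoff.r_squared_linear,
        "r_squared_hyperbolic": result.vant_hoff.r_squared_hyperbolic,
        "loo_spread": {
            k: {kk: vv for kk, vv in v.items() if kk != "values"}
            for k, v in result.vant_hoff.loo_spread.items()
        },
    }
    artifacts["thermo"] = io_mod.write_json(thermo_json, out / "thermo.json")

    kin_json = {
        "rates_per_ns": {
            f"{T:g}": {"forward": result.rates[T][0], "backward": result.rates[T][1]}
            for T in temps
        },
    }
    for name, fit in (
        ("eyring_forward", result.eyring_forward),
        ("eyring_backward", result.eyring_backward),
    ):
        if fit is not None:
            kin_json[name] = {
                "dG_dagger_kJ_mol": fit.dG_dagger,
                "c_per_ns_K": fit.c,
                "r_squared_linear": fit.r_squared_linear,
                "r_squared_exponential": fit.r_squared_exponential,
            }
    artifacts["kinetics"] = io_mod.write_json(kin_json, out / "kinetics.json")

    ent_json = {
        f"{T:g}": {
            "S_coil": e.S_coil,
            "S_globule": e.S_globule,
            "dS_pol": e.dS_pol,
            "loo_spread": e.loo_spread,
            "degenerate_dihedrals": e.degenerate_dihedrals,
        }
        for T, e in result.entropy.items()
    }
    artifacts["entropy"] = io_mod.write_json(ent_json, out / "entropy.json")

    cat = result.catalog
    cat_json = {
        "reference_positions": {n: p for n, p in cat.reference_positions.items()},
        "macrostate": cat.macrostate,
        "membership": {
            f"{T:g}": {str(h): n for h, n in m.items()}
            for T, m in cat.membership.items()
        },
        "unmatched_flags": cat.unmatched_flags,
    }
    artifacts["substates"] = io_mod.write_json(cat_json, out / "substates.json")
    artifacts["occupancies"] = io_mod.write_csv(
        result.occupancies, out / "occupancies.csv"
    )

    if result.profiles:
        prof_rows = []
        for T in sorted(result.profiles):
            p = result.profiles[T]
            for x, F, c in zip(p.bin_centers, p.free_energy, p.counts):
                prof_rows.append(
                    {"temperature": T, "rg_nm": x,
                     "free_energy_kJ_mol": F, "count": int(c)}
                )
        artifacts["profiles"] = io_mod.write_csv(
            pd.DataFrame(prof_rows), out / "profiles.csv"
        )

    if config.write_frame_tables:
        labels_df = result.descriptors[["temperature", "replica", "frame"]].copy()
        labels_df["macrostate"] = result.macro_labels
        artifacts["macrostates"] = io_mod.write_csv(
            labels_df, out / "macrostates.csv"
        )
        artifacts["descriptors"] = io_mod.write_csv(
            result.descriptors, out / "descriptors.csv"
        )

    cfg = asdict(config)
    artifacts["manifest"] = io_mod.write_manifest(
        out, cfg, artifacts, {"all": "ok"}
    )
    return artifacts
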