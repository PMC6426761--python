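"""Naive per-cell reference implementation of the lineage engine.

Processes one cell at a time with scalar RNG draws, consuming the random
stream in the engine's documented phase order (generation-major; within a
generation: division bases with pass-based redraws, per-daughter division
noise, death factors, then the three marker-factor blocks, all row-major).
Used as the independent oracle for the vectorized engine's bookkeeping:
lineage links, fates, inheritance arithmetic and draw accounting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cytonx.config import ModelConfig
from cytonx.distributions import logspace_params_from_moments

FATES = ("divided", "died", "alive_at_horizon", "quiescent")


def _lp(mean, sd):
    return logspace_params_from_moments(mean, sd)


def simulate_reference(config: ModelConfig) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed)
    loc_mp, sc_mp = _lp(config.mu_mp, config.v_mp_eff)
    loc_p, sc_p = _lp(config.mu_p, config.v_p_eff)
    loc_md, sc_md = _lp(config.mu_md, config.sigma_md_eff)
    loc_d, sc_d = _lp(config.mu_d, config.sigma_d_eff)
    loc_a, sc_a = _lp(config.mu_a, config.v_a_eff)
    mk = config.markers
    n0 = config.n_naive
    horizon = config.horizon
    t_min = config.t_min

    destinies = None
    if config.has_destiny:
        drng = np.random.default_rng([config.seed, 1])
        if config.destiny_parameterization == "log_space":
            dloc, dsc = config.mu_div, config.v_div
        else:
            dloc, dsc = _lp(config.mu_div, config.v_div)
        destinies = [drng.lognormal(dloc, dsc) for _ in range(n0)]

    # generation 0, phase order: bases (+ redraw passes), activation, t_d0, markers
    bases = [rng.lognormal(loc_mp, sc_mp) for _ in range(n0)]
    offenders = [i for i in range(n0) if bases[i] < t_min]
    while offenders:
        for i in offenders:
            bases[i] = rng.lognormal(loc_mp, sc_mp)
        offenders = [i for i in offenders if bases[i] < t_min]
    activation = [0.0] * n0
    if config.has_activation:
        activation = [rng.lognormal(loc_a, sc_a) for _ in range(n0)]
    t_d0 = [rng.lognormal(loc_md, sc_md) for _ in range(n0)]
    if config.has_activation and config.death_clock_includes_activation:
        t_d0 = [d + a for d, a in zip(t_d0, activation)]
    cd62l = [max(rng.normal(mk.init_mean_cd62l, mk.init_sd), 0.0) for _ in range(n0)]
    cd27 = [max(rng.normal(mk.init_mean_cd27, mk.init_sd), 0.0) for _ in range(n0)]
    klrg1 = [max(rng.normal(mk.init_mean_klrg1, mk.init_sd), 0.0) for _ in range(n0)]

    # one dict per live cell of the current generation, in creation order
    gen = [
        {
            "cell_id": i, "family_id": i, "parent_id": -1, "generation": 0,
            "birth_time": 0.0, "t_p": bases[i] + activation[i], "t_p_base": bases[i],
            "t_d": t_d0[i], "cd62l": cd62l[i], "cd27": cd27[i], "klrg1": klrg1[i],
        }
        for i in range(n0)
    ]

    rows = []
    next_id = n0
    g = 0
    while True:
        mothers = []
        for cell in gen:
            if destinies is not None and cell["generation"] + 1 > destinies[cell["family_id"]]:
                fate, end = "quiescent", horizon
            elif cell["t_p"] <= cell["t_d"] and cell["birth_time"] + cell["t_p"] <= horizon:
                fate, end = "divided", cell["birth_time"] + cell["t_p"]
            elif cell["t_d"] < cell["t_p"] and cell["birth_time"] + cell["t_d"] <= horizon:
                fate, end = "died", cell["birth_time"] + cell["t_d"]
            else:
                fate, end = "alive_at_horizon", horizon
            cell["fate"], cell["end_time"] = fate, end
            rows.append(cell)
            if fate == "divided":
                mothers.append(cell)
        if not mothers:
            break
        # phase 1: shared bases with pass-based redraws
        bases = [m["t_p_base"] * rng.lognormal(loc_p, sc_p) for m in mothers]
        offenders = [i for i in range(len(mothers)) if bases[i] < t_min]
        while offenders:
            for i in offenders:
                bases[i] = mothers[i]["t_p_base"] * rng.lognormal(loc_p, sc_p)
            offenders = [i for i in offenders if bases[i] < t_min]
        # phase 2: per-daughter division noise
        eps = [[max(rng.normal(1.0, config.v_e), 0.0) for _ in range(2)] for _ in mothers]
        # phase 3: per-daughter death factors
        dfac = [[rng.lognormal(loc_d, sc_d) for _ in range(2)] for _ in mothers]
        # phases 4-6: marker factors
        f62 = [[max(rng.normal(mk.cd62l_factor_mean, mk.cd62l_factor_sd), 0.0)
                for _ in range(2)] for _ in mothers]
        f27 = [[max(rng.normal(mk.cd27_factor_mean, mk.cd27_factor_sd), 0.0)
                for _ in range(2)] for _ in mothers]
        fkl = [[max(rng.normal(mk.klrg1_factor_mean, mk.klrg1_factor_sd), 0.0)
                for _ in range(2)] for _ in mothers]
        new_gen = []
        for i, m in enumerate(mothers):
            for j in range(2):
                t_p = bases[i] * eps[i][j]
                new_gen.append(
                    {
                        "cell_id": next_id, "family_id": m["family_id"],
                        "parent_id": m["cell_id"], "generation": g + 1,
                        "birth_time": m["end_time"], "t_p": t_p, "t_p_base": t_p,
                        "t_d": m["t_d"] * dfac[i][j],
                        "cd62l": m["cd62l"] * f62[i][j],
                        "cd27": m["cd27"] * f27[i][j],
                        "klrg1": m["klrg1"] * fkl[i][j],
                    }
                )
                next_id += 1
        gen = new_gen
        g += 1

    columns = [
        "cell_id", "family_id", "parent_id", "generation",
        "birth_time", "t_p", "t_d", "fate", "end_time", "cd62l", "cd27", "klrg1",
    ]
    df = pd.DataFrame(rows)[columns]
    df["fate"] = pd.Categorical(df["fate"], categories=list(FATES))
    for col in ("cell_id", "family_id", "parent_id", "generation"):
        df[col] = df[col].astype(np.int64)
    return df.reset_index(drop=True)
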