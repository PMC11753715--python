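import numpy as np
import pandas as pd
import pytest

from karyoevolve import covsex, simdata

STAR_TREE = "(Tcas:0.0,Pcha:1.0,Ppyr:1.0,Caen:1.0,Dpon:1.0);"
LADDER_TREE = "(Tcas:0.0,((Pcha:1.0,Ppyr:1.0):0.5,(Caen:1.0,Dpon:1.0):0.5):0.2);"


@pytest.fixture
def small_history():
    """Five tips, nine elements, a handful of fusions/fissions, event-free focal."""
    return simdata.simulate_karyotype_history(
        LADDER_TREE, n_elements=9, genes_per_element=50,
        fusion_rate=0.7, fission_rate=0.5, seed=3,
    )


def simulate_step_chromosome(
    seed: int,
    n_left: int = 50,
    n_right: int = 50,
    theta_right: float = 0.8,
    depth_f: float = 20.0,
    depth_m: float = 30.0,
    dispersion: float = 10.0,
    n_autosomal: int = 200,
    window_size: int = 50_000,
):
    """One chromosome with an anc-X (theta=0) left arm and a neo-X right arm,
    plus an autosomal background; returns the FM ratio table and the true
    boundary index."""
    p_left = simdata.CoverageSimParams(
        window_size=window_size, mean_depth_f=depth_f, mean_depth_m=depth_m,
        dispersion=dispersion, theta=0.0, seed=seed,
    )
    p_right = simdata.CoverageSimParams(
        window_size=window_size, mean_depth_f=depth_f, mean_depth_m=depth_m,
        dispersion=dispersion, theta=theta_right, seed=seed + 10_000,
    )
    base = simdata.simulate_coverage(
        {"auto": [("autosome", n_autosomal)], "chrX": [("ancX", n_left)]}, p_left
    )
    right = simdata.simulate_coverage({"chrR": [("neoX", n_right)]}, p_right)
    shift = n_left * window_size

    def _append(track_left: pd.DataFrame, track_right: pd.DataFrame) -> pd.DataFrame:
        moved = track_right.assign(
            chrom="chrX", start=track_right["start"] + shift, end=track_right["end"] + shift
        )
        return pd.concat([track_left, moved], ignore_index=True)

    female = _append(base.female, right.female)
    male = _append(base.male, right.male)
    table = covsex.fm_ratio(female, male)
    return table, n_left


def brute_force_breakpoint(values: np.ndarray) -> tuple[int, float]:
    """Independent O(n^2) re-implementation of the single least-squares split."""
    n = len(values)
    best_b, best_cost = None, np.inf
    for b in range(1, n):
        left, right = values[:b], values[b:]
        cost = (
            float(np.sum((left - left.mean()) ** 2))
            + float(np.sum((right - right.mean()) ** 2))
        )
        if cost < best_cost:
            best_b, best_cost = b, cost
    return best_b, best_cost
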