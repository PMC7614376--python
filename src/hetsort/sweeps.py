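"""Parameter sweeps, Gaussian-process surrogates and transition contours.

The phase behaviour of a network family is mapped in the
(g_coup, G, sortedness) box by Monte-Carlo sampling: each sample draws a
fresh graph (WS) or uses the fixed lattice (betaC), a fresh random
partition sorted forward to convergence, picks the partition at a
sampled iteration fraction, runs the dynamics from fresh initial
conditions, and records the features.  A Gaussian-process regression
fitted to the resulting table provides a smooth surrogate of P_bar or
R_bar over (G, A) (or the full 3-D box), from which half-maximum
contours/isosurfaces locate the quiescence-to-activity transition.

Desk-scale presets use reduced graphs (WS N=250, betaC N=347) and
sample counts so a sweep completes on one CPU in minutes; the full-
scale presets (thousands of samples at N~1000) are provided as
configurations intended for cluster runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .graphs import BC_N, BC_N_DESK, Graph, make_bc_lattice, make_ws_graph
from .netsim import NetworkModel, sample_initial_conditions, simulate_network
from .node_models import FHNParams, SRKParams
from .sortedness import Partition, network_sortedness, random_partition, sort_network
from .features import summarise

__all__ = [
    "SweepDesign",
    "SurrogateSurface",
    "latin_hypercube",
    "run_sweep",
    "run_transition_scan",
    "half_max_drive",
    "fit_surrogate",
    "half_max_contour",
    "DESK_PRESETS",
]

Family = Literal["WS-FHN", "WS-SRK", "betaC-FHN", "betaC-SRK"]

#: Full-scale study conditions per family: drive and coupling ranges,
#: strong-coupling values, and per-population excitability.
FAMILY_CONDITIONS = {
    "FHN": {
        "G_range": (0.15, 0.34),
        "g_coup_range": (0.02, 0.1),
        "g_coup_strong": 0.1,
        "pop_params": {1: {"I": 2.0}, 2: {"I": 1.0}},
    },
    "SRK": {
        "G_range": (0.2, 0.6),
        "g_coup_range": (2.0, 10.0),
        "g_coup_strong": 10.0,
        "pop_params": {1: {"gL": 60.0}, 2: {"gL": 100.0}},
    },
}

FRAC_POP1 = 0.1


@dataclass
class SweepDesign:
    """A Latin-hypercube experiment over (g_coup, G, a_fraction).

    ``g_coup_range`` may be a (lo, hi) interval (3-D design) or a single
    fixed value (2-D design over (G, a)).  The sorting-iteration axis is
    sampled as a fraction of each sample's own a_final, making samples
    with different convergence lengths comparable.
    """

    family: Family
    n_samples: int
    G_range: tuple[float, float]
    g_coup_range: tuple[float, float] | float
    a_frac_range: tuple[float, float] = (0.0, 1.0)
    graph_params: dict = field(default_factory=dict)
    frac_pop1: float = FRAC_POP1
    scale: str = "desk"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.G_range[0] >= self.G_range[1]:
            raise ValueError("G_range must be non-degenerate")

    @property
    def dims(self) -> list[str]:
        d = ["G", "a_frac"]
        if not np.isscalar(self.g_coup_range):
            d.insert(0, "g_coup")
        return d

    @classmethod
    def preset(cls, name: str) -> "SweepDesign":
        try:
            return DESK_PRESETS[name]()
        except KeyError:
            raise KeyError(
                f"unknown preset {name!r}; available: {sorted(DESK_PRESETS)}"
            ) from None


def latin_hypercube(design: SweepDesign, seed: int) -> np.ndarray:
    """Stratified sample of the design box, shape (n_samples, n_dims).

    Each marginal places exactly one point in each of n_samples equal
    strata (the defining property of a Latin hypercube).
    """
    dims = design.dims
    if design.n_samples < len(dims):
        raise ValueError("n_samples must be >= number of design dimensions")
    sampler = qmc.LatinHypercube(d=len(dims), seed=seed)
    u = sampler.random(design.n_samples)
    lows, highs = [], []
    for name in dims:
        if name == "G":
            lo, hi = design.G_range
        elif name == "g_coup":
            lo, hi = design.g_coup_range
        else:
            lo, hi = design.a_frac_range
        lows.append(lo)
        highs.append(hi)
    return qmc.scale(u, lows, highs)


def _build_graph(design: SweepDesign, seed: int) -> Graph:
    gfamily = design.family.split("-")[0]
    gp = design.graph_params
    if gfamily == "WS":
        return make_ws_graph(
            N=gp.get("N", 250 if design.scale == "desk" else 1000),
            D=gp.get("D", 12),
            beta=gp.get("beta", 0.2),
            seed=seed,
        )
    return make_bc_lattice(
        n_nodes=gp.get("N", BC_N_DESK if design.scale == "desk" else BC_N)
    )


def _build_model(
    design: SweepDesign, graph: Graph, partition: Partition, g_coup: float, G: float
) -> NetworkModel:
    mfamily = design.family.split("-")[1]
    cond = FAMILY_CONDITIONS[mfamily]
    if mfamily == "FHN":
        pop_params = {k: FHNParams(**v) for k, v in cond["pop_params"].items()}
        kind = "fhn"
    else:
        pop_params = {k: SRKParams(**v) for k, v in cond["pop_params"].items()}
        kind = "srk"
    return NetworkModel(
        kind=kind, graph=graph, partition=partition,
        pop_params=pop_params, g_coup=g_coup, G=G,
    )


def _sim_options(design: SweepDesign) -> dict:
    """Desk-scale integration horizons (full scale uses module defaults)."""
    if design.scale != "desk":
        return {}
    if design.family.endswith("FHN"):
        return {"t_span": (0.0, 400.0), "n_out": 1600}
    return {"t_span": (0.0, 150_000.0), "n_out": 10000}


def run_sweep(
    design: SweepDesign,
    seed: int,
    checkpoint: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Execute a Latin-hypercube sweep; one row per sample.

    Per sample: fresh graph (WS) or fixed lattice (betaC), fresh random
    partition, forward sort to convergence, partition at the sampled
    iteration fraction, fresh initial conditions, simulate, features.
    Deterministic under a fixed seed.  With ``checkpoint`` set, finished
    rows are appended to a CSV and a restarted call skips them.
    """
    points = latin_hypercube(design, seed)
    dims = design.dims
    fixed_g = float(design.g_coup_range) if np.isscalar(design.g_coup_range) else None

    done: set[int] = set()
    rows: list[dict] = []
    if checkpoint is not None and Path(checkpoint).exists():
        prev = pd.read_csv(checkpoint)
        # empty error strings round-trip through CSV as NaN
        prev["error"] = prev["error"].fillna("").astype(str)
        rows = prev.to_dict("records")
        done = set(prev["sample"].astype(int))

    master = np.random.SeedSequence([seed, 0x5EED])
    sample_seeds = master.spawn(design.n_samples)

    for s in range(design.n_samples):
        if s in done:
            continue
        pt = dict(zip(dims, points[s]))
        g_coup = fixed_g if fixed_g is not None else float(pt["g_coup"])
        G, a_frac = float(pt["G"]), float(pt["a_frac"])
        ss = sample_seeds[s]
        r_graph, r_part, r_sort, r_ic = ss.spawn(4)
        try:
            graph = _build_graph(design, seed=int(r_graph.generate_state(1)[0] % 2**31))
            partition0 = random_partition(
                graph.N, design.frac_pop1, np.random.default_rng(r_part)
            )
            trace = sort_network(
                graph, partition0, direction="forward",
                rng=np.random.default_rng(r_sort),
            )
            a = int(round(a_frac * trace.a_final))
            partition = Partition(trace.labels_at(a))
            A = trace.sortedness_values[a]
            model = _build_model(design, graph, partition, g_coup, G)
            Y0 = sample_initial_conditions(model, np.random.default_rng(r_ic))
            sim = simulate_network(model, Y0, **_sim_options(design))
            feats = summarise(sim, partition)
            row = {
                "sample": s, "g_coup": g_coup, "G": G, "a": a,
                "a_frac": a_frac, "a_final": trace.a_final, "A": A,
                **feats.as_dict(), "error": "",
            }
        except Exception as exc:  # individual failures recorded, not fatal
            row = {
                "sample": s, "g_coup": g_coup, "G": G, "a": -1,
                "a_frac": a_frac, "a_final": -1, "A": np.nan,
                "error": f"{type(exc).__name__}: {exc}",
            }
        rows.append(row)
        if checkpoint is not None:
            pd.DataFrame(rows).to_csv(checkpoint, index=False)
    return pd.DataFrame(rows).sort_values("sample").reset_index(drop=True)


def run_transition_scan(
    family: Family,
    G_values: Sequence[float],
    seed: int,
    g_coup: Optional[float] = None,
    scale: str = "desk",
    graph_params: Optional[dict] = None,
) -> pd.DataFrame:
    """Drive scan at fixed strong coupling for random vs fully sorted labels.

    One graph, one random partition, one forward sorting run; the
    dynamics are then simulated over ``G_values`` for the partitions at
    a = 0 and a = a_final with a shared set of initial conditions.
    Returns a tidy frame with one row per (G, partition state).
    """
    design = SweepDesign(
        family=family, n_samples=1,
        G_range=FAMILY_CONDITIONS[family.split("-")[1]]["G_range"],
        g_coup_range=0.0, scale=scale, graph_params=graph_params or {},
    )
    if g_coup is None:
        g_coup = FAMILY_CONDITIONS[family.split("-")[1]]["g_coup_strong"]

    master = np.random.SeedSequence([seed, 0x7CAB])
    r_graph, r_part, r_sort, r_ic = master.spawn(4)
    graph = _build_graph(design, seed=int(r_graph.generate_state(1)[0] % 2**31))
    partition0 = random_partition(graph.N, FRAC_POP1, np.random.default_rng(r_part))
    trace = sort_network(
        graph, partition0, direction="forward", rng=np.random.default_rng(r_sort)
    )
    states = {"random": 0, "sorted": trace.a_final}

    rows = []
    for label, a in states.items():
        partition = Partition(trace.labels_at(a))
        A = trace.sortedness_values[a]
        model0 = _build_model(design, graph, partition, g_coup, float(G_values[0]))
        Y0 = sample_initial_conditions(model0, np.random.default_rng(r_ic))
        for G in G_values:
            model = _build_model(design, graph, partition, g_coup, float(G))
            sim = simulate_network(model, Y0, **_sim_options(design))
            feats = summarise(sim, partition)
            rows.append(
                {"state": label, "a": a, "A": A, "G": float(G), "g_coup": g_coup,
                 **feats.as_dict()}
            )
    return pd.DataFrame(rows)


def half_max_drive(df: pd.DataFrame, feature: str = "P_bar") -> dict[str, float]:
    """Drive G at which a feature crosses half its maximum, per state.

    Linear interpolation between the last sub-threshold and first
    supra-threshold G along the scan.  NaN when the state never crosses.
    """
    out = {}
    level = 0.5 * df[feature].max()
    for label, sub in df.groupby("state"):
        sub = sub.sort_values("G")
        g, y = sub["G"].to_numpy(), sub[feature].to_numpy()
        above = y >= level
        if not above.any() or above.all():
            out[label] = float("nan")
            continue
        k = int(np.argmax(above))
        if k == 0:
            out[label] = float(g[0])
        else:
            f = (level - y[k - 1]) / (y[k] - y[k - 1])
            out[label] = float(g[k - 1] + f * (g[k] - g[k - 1]))
    return out


# --------------------------------------------------------------------------
# Gaussian-process surrogate
# --------------------------------------------------------------------------

@dataclass
class SurrogateSurface:
    """A fitted GP over standardised inputs plus a prediction grid."""

    gp: object
    input_names: list[str]
    x_mean: np.ndarray
    x_std: np.ndarray
    grid_axes: list[np.ndarray]
    field: np.ndarray
    feature: str

    def predict(self, X: np.ndarray, return_std: bool = False):
        Xs = (np.atleast_2d(X) - self.x_mean) / self.x_std
        return self.gp.predict(Xs, return_std=return_std)


def fit_surrogate(
    table: pd.DataFrame,
    feature: str = "P_bar",
    inputs: Sequence[str] = ("G", "A"),
    grid_size: int = 40,
    n_restarts: int = 2,
    random_state: int = 0,
) -> SurrogateSurface:
    """Fit an anisotropic RBF + white-noise GP and predict on a grid.

    Inputs are standardised to zero mean and unit variance; the target
    is normalised internally by the regressor.  Requires >= 20 rows and
    non-degenerate input columns.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

    ok = table["error"].fillna("").eq("") if "error" in table else np.ones(len(table), bool)
    sub = table[ok].dropna(subset=list(inputs) + [feature])
    if len(sub) < 20:
        raise ValueError(f"need >= 20 valid rows to fit a surrogate, have {len(sub)}")
    X = sub[list(inputs)].to_numpy(dtype=float)
    y = sub[feature].to_numpy(dtype=float)
    x_mean, x_std = X.mean(axis=0), X.std(axis=0)
    if np.any(x_std == 0):
        bad = [inputs[i] for i in np.flatnonzero(x_std == 0)]
        raise ValueError(f"degenerate (constant) input column(s): {bad}")
    Xs = (X - x_mean) / x_std

    kernel = ConstantKernel(1.0) * RBF(length_scale=np.ones(X.shape[1])) + WhiteKernel(
        noise_level=1e-2
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=True,
        n_restarts_optimizer=n_restarts,
        random_state=random_state,
    )
    gp.fit(Xs, y)

    axes = [np.linspace(X[:, d].min(), X[:, d].max(), grid_size) for d in range(X.shape[1])]
    mesh = np.meshgrid(*axes, indexing="ij")
    Xg = np.column_stack([m.ravel() for m in mesh])
    pred = gp.predict((Xg - x_mean) / x_std).reshape(mesh[0].shape)
    return SurrogateSurface(
        gp=gp, input_names=list(inputs), x_mean=x_mean, x_std=x_std,
        grid_axes=axes, field=pred, feature=feature,
    )


def half_max_contour(surface: SurrogateSurface, level: Optional[float] = None):
    """Level set of the predicted field at 0.5 * its grid maximum.

    2-D fields return a list of polylines in input coordinates; 3-D
    fields return a marching-cubes mesh (vertices in input coordinates,
    faces).  A level outside the field range yields an empty result.
    """
    if level is None:
        level = 0.5 * float(surface.field.max())
    field = surface.field
    if not (field.min() <= level <= field.max()):
        return [] if field.ndim == 2 else (np.empty((0, 3)), np.empty((0, 3), int))
    axes = surface.grid_axes
    if field.ndim == 2:
        from skimage.measure import find_contours

        lines = []
        for c in find_contours(field, level):
            x = np.interp(c[:, 0], np.arange(len(axes[0])), axes[0])
            y = np.interp(c[:, 1], np.arange(len(axes[1])), axes[1])
            lines.append(np.column_stack([x, y]))
        return lines
    if field.ndim == 3:
        from skimage.measure import marching_cubes

        verts, faces, _, _ = marching_cubes(field, level)
        out = np.empty_like(verts)
        for d in range(3):
            out[:, d] = np.interp(verts[:, d], np.arange(len(axes[d])), axes[d])
        return out, faces
    raise ValueError(f"unsupported field dimensionality {field.ndim}")


# --------------------------------------------------------------------------
# Presets
# --------------------------------------------------------------------------

def _build_presets() -> dict:
    def ws_fhn_desk():
        return SweepDesign(
            family="WS-FHN", n_samples=60,
            G_range=(0.15, 0.34), g_coup_range=0.1, scale="desk",
        )

    def bc_fhn_desk():
        return SweepDesign(
            family="betaC-FHN", n_samples=60,
            G_range=(0.15, 0.34), g_coup_range=0.1, scale="desk",
        )

    def ws_fhn_3d_desk():
        return SweepDesign(
            family="WS-FHN", n_samples=80,
            G_range=(0.15, 0.34), g_coup_range=(0.02, 0.1), scale="desk",
        )

    # full-scale presets: cluster-sized sample counts at N ~ 1000
    def ws_fhn_full():
        return SweepDesign(
            family="WS-FHN", n_samples=10_000,
            G_range=(0.15, 0.34), g_coup_range=0.1, scale="full",
        )

    def ws_srk_full():
        return SweepDesign(
            family="WS-SRK", n_samples=5_000,
            G_range=(0.2, 0.6), g_coup_range=10.0, scale="full",
        )

    def ws_fhn_3d_full():
        return SweepDesign(
            family="WS-FHN", n_samples=20_000,
            G_range=(0.15, 0.34), g_coup_range=(0.02, 0.1), scale="full",
        )

    def ws_srk_3d_full():
        return SweepDesign(
            family="WS-SRK", n_samples=10_000,
            G_range=(0.2, 0.6), g_coup_range=(2.0, 10.0), scale="full",
        )

    return {
        "ws-fhn-desk": ws_fhn_desk,
        "bc-fhn-desk": bc_fhn_desk,
        "ws-fhn-3d-desk": ws_fhn_3d_desk,
        "ws-fhn-full": ws_fhn_full,
        "ws-srk-full": ws_srk_full,
        "ws-fhn-3d-full": ws_fhn_3d_full,
        "ws-srk-3d-full": ws_srk_3d_full,
    }


DESK_PRESETS = _build_presets()
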