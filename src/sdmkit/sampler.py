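"""Lambda/temperature Hamiltonian replica-exchange Monte Carlo on toy models.

Each replica carries one ligand configuration (a 3-vector relative to the
receptor origin) and holds exactly one state of the (lambda, T) grid; the
state-to-replica assignment is a permutation at all times.  Propagation is a
Metropolis random walk against the reduced coupled potential plus the
flat-bottom site restraint; state exchanges between grid-adjacent replicas
follow the standard Metropolis swap criterion, alternating sweeps over
nearest neighbors in the lambda dimension and in the temperature dimension
with even/odd pairing.

Binding-energy samples are recorded with a fixed period as
(time, replica, lambda, T, u0, u) records; the "time" column counts sweeps
(abstract units -- a 25 ps/sample labeling is a convention of the molecular
runs this emulates, not of this engine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .alchemical import (
    DEFAULT_UMAX,
    AlchemicalState,
    InvalidInputError,
    StateGrid,
    flat_bottom_restraint,
    softcore_transform,
)

__all__ = ["Replica", "SampleSet", "mc_propagate", "attempt_swap", "run_hrem"]

SAMPLE_COLUMNS = (
    "time",
    "replica",
    "lambda",
    "temperature_K",
    "U0_kcal_mol",
    "u_kcal_mol",
)


@dataclass
class Replica:
    """One replica: a ligand position and the index of the grid state it
    currently holds."""

    position: np.ndarray
    state_index: int

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)


@dataclass
class SampleSet:
    """Tagged binding-energy time series over a state grid.

    ``data`` holds one row per (sample event, replica) with columns
    ``time, replica, lambda, temperature_K, U0_kcal_mol, u_kcal_mol``;
    ``meta`` carries provenance (seed, model hash, schedule).
    """

    data: pd.DataFrame
    grid: StateGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidInputError(f"sample table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        """Check grid membership and per-replica time monotonicity."""
        lam = self.data["lambda"].to_numpy()
        temp = self.data["temperature_K"].to_numpy()
        self.state_indices()  # raises on rows outside the grid
        del lam, temp
        for rep, sub in self.data.groupby("replica"):
            t = sub["time"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise InvalidInputError(
                    f"time not strictly increasing for replica {rep}"
                )

    def state_indices(self) -> np.ndarray:
        """Flattened grid state index of every record."""
        lams = np.asarray(self.grid.lambdas)
        temps = np.asarray(self.grid.temperatures)
        il = np.searchsorted(lams, self.data["lambda"].to_numpy())
        il = np.clip(il, 0, len(lams) - 1)
        # searchsorted gives the right insertion point; snap to nearest value
        lo = np.clip(il - 1, 0, len(lams) - 1)
        il = np.where(
            np.abs(lams[lo] - self.data["lambda"].to_numpy())
            < np.abs(lams[il] - self.data["lambda"].to_numpy()),
            lo,
            il,
        )
        it = np.searchsorted(temps, self.data["temperature_K"].to_numpy())
        it = np.clip(it, 0, len(temps) - 1)
        lo = np.clip(it - 1, 0, len(temps) - 1)
        it = np.where(
            np.abs(temps[lo] - self.data["temperature_K"].to_numpy())
            < np.abs(temps[it] - self.data["temperature_K"].to_numpy()),
            lo,
            it,
        )
        bad_l = np.abs(lams[il] - self.data["lambda"].to_numpy()) > 1e-9
        bad_t = np.abs(temps[it] - self.data["temperature_K"].to_numpy()) > 1e-9
        bad = bad_l | bad_t
        if np.any(bad):
            rows = np.nonzero(bad)[0][:5]
            raise InvalidInputError(
                f"rows with (lambda, T) outside the declared grid at indices "
                f"{rows.tolist()}"
            )
        return it * self.grid.n_lambda + il

    def counts(self) -> np.ndarray:
        """Sample count per grid state, shape (n_states,)."""
        return np.bincount(self.state_indices(), minlength=self.grid.n_states)

    def for_state(
        self, lam: float, temperature: float, t_min: float = -np.inf,
        t_max: float = np.inf,
    ) -> pd.DataFrame:
        """Records belonging to one (lambda, T) state within a time window."""
        d = self.data
        m = (
            (np.abs(d["lambda"] - lam) <= 1e-9)
            & (np.abs(d["temperature_K"] - temperature) <= 1e-9)
            & (d["time"] >= t_min)
            & (d["time"] <= t_max)
        )
        return d.loc[m]

    def time_window(self, t_min: float = -np.inf, t_max: float = np.inf) -> "SampleSet":
        d = self.data
        m = (d["time"] >= t_min) & (d["time"] <= t_max)
        return SampleSet(d.loc[m].reset_index(drop=True), self.grid, dict(self.meta))


# ---------------------------------------------------------------------------
# Energies


def _reduced_energy(
    model, r: np.ndarray, lam: np.ndarray, beta: np.ndarray, u_max: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-replica (reduced total energy, u0, raw u) at radial distances r."""
    u = model.energy_radial(r)
    u0 = np.full_like(u, model.u0_value)
    w = flat_bottom_restraint(r, model.site)
    red = beta * (u0 + lam * softcore_transform(u, u_max) + w)
    return red, u0, u


def mc_propagate(
    replica: Replica,
    model,
    state: AlchemicalState,
    n_steps: int,
    step_size: float,
    rng: np.random.Generator,
    u_max: float = DEFAULT_UMAX,
) -> Replica:
    """Metropolis random-walk propagation of one replica.

    Isotropic uniform-cube displacement proposals of half-width
    ``step_size``; acceptance against the reduced coupled potential plus the
    site restraint, which satisfies detailed balance move by move.  Returns a
    new Replica (the input is not modified).
    """
    if step_size < 0:
        raise InvalidInputError("step_size must be non-negative")
    x = replica.position.copy()
    lam = np.array([state.lam])
    beta = np.array([state.beta])
    r = np.array([np.linalg.norm(x)])
    e, _, _ = _reduced_energy(model, r, lam, beta, u_max)
    for _ in range(int(n_steps)):
        prop = x + rng.uniform(-step_size, step_size, size=3)
        rp = np.array([np.linalg.norm(prop)])
        ep, _, _ = _reduced_energy(model, rp, lam, beta, u_max)
        if np.log(rng.random()) < e[0] - ep[0]:
            x, e = prop, ep
    return Replica(x, replica.state_index)


def attempt_swap(
    rep_i: Replica,
    rep_j: Replica,
    grid: StateGrid,
    model,
    rng: np.random.Generator,
    u_max: float = DEFAULT_UMAX,
) -> bool:
    """Metropolis exchange of the states held by two grid-adjacent replicas.

    The pair must differ by one step in exactly one grid dimension.  Accepts
    with min(1, exp(-Delta)), Delta being the reduced-energy cost of
    evaluating each configuration under the other state; on acceptance the
    replicas' state indices are exchanged in place.
    """
    ia, ib = rep_i.state_index, rep_j.state_index
    (ti, li), (tj, lj) = grid.unravel(ia), grid.unravel(ib)
    if not (abs(ti - tj) + abs(li - lj) == 1):
        raise InvalidInputError(
            f"states {ia} and {ib} are not nearest neighbors in one dimension"
        )
    lam = np.array([grid.lam_of_states()[ia], grid.lam_of_states()[ib]])
    beta = np.array([grid.beta_of_states()[ia], grid.beta_of_states()[ib]])
    r = np.array(
        [np.linalg.norm(rep_i.position), np.linalg.norm(rep_j.position)]
    )
    # energies of both configurations in both states
    e_ii, _, _ = _reduced_energy(model, r[:1], lam[:1], beta[:1], u_max)
    e_jj, _, _ = _reduced_energy(model, r[1:], lam[1:], beta[1:], u_max)
    e_ij, _, _ = _reduced_energy(model, r[:1], lam[1:], beta[1:], u_max)
    e_ji, _, _ = _reduced_energy(model, r[1:], lam[:1], beta[:1], u_max)
    delta = (e_ij[0] + e_ji[0]) - (e_ii[0] + e_jj[0])
    accept = bool(np.log(rng.random()) < -delta) if np.isfinite(delta) else delta < 0
    if accept:
        rep_i.state_index, rep_j.state_index = ib, ia
    return accept


def _swap_sweep(
    state_of_replica: np.ndarray,
    red_matrix_cols: np.ndarray,
    grid: StateGrid,
    dim: str,
    parity: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized even/odd neighbor exchange along one grid dimension.

    ``red_matrix_cols[k, i]`` is the reduced energy of replica i's current
    configuration evaluated in grid state k.  Returns the updated
    state_of_replica permutation.
    """
    n_lam, n_temp = grid.n_lambda, grid.n_temperature
    replica_of_state = np.empty_like(state_of_replica)
    replica_of_state[state_of_replica] = np.arange(len(state_of_replica))
    pairs = []
    if dim == "lambda":
        for it in range(n_temp):
            for il in range(parity, n_lam - 1, 2):
                pairs.append((it * n_lam + il, it * n_lam + il + 1))
    else:
        for il in range(n_lam):
            for it in range(parity, n_temp - 1, 2):
                pairs.append((it * n_lam + il, (it + 1) * n_lam + il))
    if not pairs:
        return state_of_replica
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    ra, rb = replica_of_state[a], replica_of_state[b]
    delta = (
        red_matrix_cols[b, ra]
        + red_matrix_cols[a, rb]
        - red_matrix_cols[a, ra]
        - red_matrix_cols[b, rb]
    )
    accept = np.log(rng.random(len(pairs))) < -delta
    sw_a, sw_b = ra[accept], rb[accept]
    state_of_replica[sw_a], state_of_replica[sw_b] = (
        state_of_replica[sw_b].copy(),
        state_of_replica[sw_a].copy(),
    )
    return state_of_replica


def run_hrem(
    model,
    grid: StateGrid,
    n_sweeps: int,
    swap_period: int = 2,
    sample_period: int = 10,
    seed: int = 0,
    step_size: float = 1.0,
    u_max: float = DEFAULT_UMAX,
    moves_per_sweep: int = 1,
    burn_in: int = 0,
) -> SampleSet:
    """Replica-exchange run over the full grid, one replica per state.

    A sweep applies ``moves_per_sweep`` Metropolis moves to every replica
    (vectorized); every ``swap_period`` sweeps one exchange phase runs,
    cycling through lambda-even, lambda-odd, T-even, T-odd neighbor pairings;
    every ``sample_period`` sweeps one (u0, u) record per state is emitted.
    Fully reproducible from ``seed`` (counter-based Philox generator).
    ``burn_in`` sweeps run before sampling starts (time still counts them).
    """
    if grid.lambdas[0] != 0.0 or grid.lambdas[-1] != 1.0:
        raise InvalidInputError("grid must include lambda = 0 and lambda = 1")
    if swap_period < 1 or sample_period < 1:
        raise InvalidInputError("periods must be >= 1")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    k = grid.n_states
    lam_all = grid.lam_of_states()
    beta_all = grid.beta_of_states()
    # initial positions uniform in the site sphere; state i held by replica i
    radius = model.site.radius
    pos = rng.uniform(-radius, radius, size=(k, 3))
    bad = np.linalg.norm(pos, axis=1) > radius
    while np.any(bad):
        pos[bad] = rng.uniform(-radius, radius, size=(int(bad.sum()), 3))
        bad = np.linalg.norm(pos, axis=1) > radius
    state_of_replica = np.arange(k)

    r = np.linalg.norm(pos, axis=1)
    e_cur, u0_cur, u_cur = _reduced_energy(
        model, r, lam_all[state_of_replica], beta_all[state_of_replica], u_max
    )

    records: list[np.ndarray] = []
    swap_phase = 0
    for sweep in range(1, int(n_sweeps) + 1):
        for _ in range(int(moves_per_sweep)):
            prop = pos + rng.uniform(-step_size, step_size, size=(k, 3))
            rp = np.linalg.norm(prop, axis=1)
            e_new, u0_new, u_new = _reduced_energy(
                model, rp, lam_all[state_of_replica], beta_all[state_of_replica],
                u_max,
            )
            acc = np.log(rng.random(k)) < e_cur - e_new
            pos[acc] = prop[acc]
            e_cur = np.where(acc, e_new, e_cur)
            u_cur = np.where(acc, u_new, u_cur)
            u0_cur = np.where(acc, u0_new, u0_cur)
        if sweep % swap_period == 0 and k > 1:
            # reduced energy of every replica in every state, from cached
            # (u0, softcore u, restraint) pieces
            r = np.linalg.norm(pos, axis=1)
            sc = softcore_transform(u_cur, u_max)
            w = flat_bottom_restraint(r, model.site)
            red_cols = beta_all[:, None] * (
                u0_cur[None, :] + lam_all[:, None] * sc[None, :] + w[None, :]
            )
            dim = "lambda" if swap_phase in (0, 1) else "temperature"
            parity = swap_phase % 2
            state_of_replica = _swap_sweep(
                state_of_replica, red_cols, grid, dim, parity, rng
            )
            swap_phase = (swap_phase + 1) % 4
            e_cur = beta_all[state_of_replica] * (
                u0_cur + lam_all[state_of_replica] * sc + w
            )
        if sweep % sample_period == 0 and sweep > burn_in:
            rec = np.column_stack(
                [
                    np.full(k, float(sweep)),
                    np.arange(k, dtype=float),
                    lam_all[state_of_replica],
                    1.0 / (grid.kb * beta_all[state_of_replica]),
                    u0_cur,
                    u_cur,
                ]
            )
            records.append(rec)

    if records:
        arr = np.vstack(records)
    else:
        arr = np.empty((0, 6))
    df = pd.DataFrame(arr, columns=list(SAMPLE_COLUMNS))
    df["replica"] = df["replica"].astype(int)
    meta = {
        "seed": int(seed),
        "n_sweeps": int(n_sweeps),
        "swap_period": int(swap_period),
        "sample_period": int(sample_period),
        "step_size": float(step_size),
        "u_max": float(u_max),
        "moves_per_sweep": int(moves_per_sweep),
        "model": getattr(model, "describe", lambda: repr(model))(),
        "grid": grid.to_dict(),
    }
    return SampleSet(df, grid, meta)
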