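"""Exponential-stability diagnostics for nonautonomous compartmental systems.

Two sufficient criteria are checked on a sampling grid:

* the mass system dx/dt = B(t) x is exponentially stable when, after a
  permutation, B(t) is lower block triangular for all t and every
  diagonal block is strictly diagonally dominant by rows with a uniform
  margin delta > 0;
* the mean-age system inherits exponential stability when additionally
  (a) every pool of the first block receives input flux >= delta and
  (b) every pool of a later block has an incoming rate >= delta from
  some pool of an earlier block.

The block structure is the condensation of the directed transfer graph
(edge j -> i iff b_ij(t) > tol at some sampled time) into strongly
connected components, ordered topologically.  Note the asymmetry: the
compartmental property constrains COLUMN sums of B, while the dominance
criterion constrains ROW sums of the diagonal blocks; both are checked
exactly as stated and never conflated.  The criteria are sufficient,
not necessary — a failing block can still belong to a stable system,
which ``empirical_decay`` can confirm by fitting ||Phi(t, t0)||.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core_model import CompartmentalSystem, transition_operators

__all__ = [
    "BlockStructure",
    "StabilityReport",
    "block_structure",
    "check_theorem_mass",
    "check_theorem_age",
    "empirical_decay",
]

EDGE_TOL = 1e-12


@dataclass
class BlockStructure:
    """Topologically ordered strongly connected components of the flow graph."""

    blocks: list[list[int]]          # 0-based pool indices, donor blocks first
    permutation: np.ndarray          # concatenation of blocks

    @property
    def m(self) -> int:
        return len(self.blocks)

    def triangularity_defect(self, B: np.ndarray) -> float:
        """Largest |entry| above the block diagonal of the permuted matrix."""
        P = B[np.ix_(self.permutation, self.permutation)]
        sizes = [len(b) for b in self.blocks]
        offs = np.cumsum([0] + sizes)
        worst = 0.0
        for n in range(self.m):
            upper = P[offs[n]:offs[n + 1], offs[n + 1]:]
            if upper.size:
                worst = max(worst, float(np.max(np.abs(upper))))
        return worst


@dataclass
class StabilityReport:
    """Verdicts of the block-dominance stability criteria on a sample grid."""

    structure: BlockStructure
    sample_grid: np.ndarray
    # mass-system criterion: per-block (i) diag < 0, (ii) offdiag >= 0,
    # (iii) row sums <= -delta; margins are worst cases over rows and times
    mass_conditions: list[dict] = field(default_factory=list)
    delta_estimate: float = 0.0
    # mean-age criterion: (a) first-block inputs, (b) cross-block witnesses
    age_conditions: dict | None = None
    decay: tuple[float, float] | None = None   # (K, gamma) empirical fit

    @property
    def mass_criterion_holds(self) -> bool:
        return self.delta_estimate > 0 and all(
            c["diag_negative"] and c["offdiag_nonnegative"] and c["row_sums_dominant"]
            for c in self.mass_conditions)

    @property
    def age_criterion_holds(self) -> bool:
        if self.age_conditions is None:
            return False
        a = self.age_conditions
        return self.mass_criterion_holds and a["inputs_ok"] and a["witnesses_ok"]

    def to_dict(self) -> dict:
        out = {
            "blocks": [[i + 1 for i in b] for b in self.structure.blocks],
            "mass_conditions": self.mass_conditions,
            "delta_estimate": self.delta_estimate,
            "mass_criterion_holds": self.mass_criterion_holds,
        }
        if self.age_conditions is not None:
            out["age_conditions"] = self.age_conditions
            out["age_criterion_holds"] = self.age_criterion_holds
        if self.decay is not None:
            out["decay"] = {"K": self.decay[0], "gamma": self.decay[1]}
        return out


def _union_pattern(system: CompartmentalSystem, grid, tol: float) -> np.ndarray:
    d = system.d
    pattern = np.zeros((d, d), dtype=bool)
    for t in np.asarray(grid, dtype=float):
        pattern |= np.abs(system.B_at(t)) > tol
    np.fill_diagonal(pattern, False)
    return pattern


def block_structure(
    system: CompartmentalSystem, sample_grid, tol: float = EDGE_TOL
) -> BlockStructure:
    """Find the block lower-triangular structure valid for all sampled times.

    Builds the union-over-time sparsity pattern, takes strongly connected
    components of the graph with an edge j -> i whenever b_ij(t) > tol
    at some sampled t, and orders them topologically (donors first) with
    deterministic ties broken by the smallest original pool index.
    """
    pattern = _union_pattern(system, sample_grid, tol)
    G = nx.DiGraph()
    G.add_nodes_from(range(system.d))
    for i, j in zip(*np.nonzero(pattern)):
        G.add_edge(int(j), int(i))  # mass flows j -> i when b_ij > 0

    C = nx.condensation(G)  # nodes carry 'members'
    indeg = dict(C.in_degree())
    key = {n: min(C.nodes[n]["members"]) for n in C.nodes}
    heap = [(key[n], n) for n in C.nodes if indeg[n] == 0]
    heapq.heapify(heap)
    blocks: list[list[int]] = []
    while heap:
        _, n = heapq.heappop(heap)
        blocks.append(sorted(C.nodes[n]["members"]))
        for nb in C.successors(n):
            indeg[nb] -= 1
            if indeg[nb] == 0:
                heapq.heappush(heap, (key[nb], nb))
    perm = np.concatenate([np.array(b, dtype=int) for b in blocks])
    return BlockStructure(blocks=blocks, permutation=perm)


def check_theorem_mass(
    system: CompartmentalSystem,
    sample_grid,
    tol: float = EDGE_TOL,
    structure: BlockStructure | None = None,
) -> StabilityReport:
    """Check block-wise strict row diagonal dominance of B(t).

    For each diagonal block and sampled time: (i) diagonal entries
    negative, (ii) off-diagonal entries nonnegative, (iii) every WITHIN-
    BLOCK row sum <= -delta.  ``delta_estimate`` is the largest uniform
    delta for which (iii) holds (the minimum over blocks, rows and times
    of minus the row sum), floored at 0, and set to 0 whenever (i) or
    (ii) fails.  Failure is a report outcome, never an exception.
    """
    grid = np.asarray(sample_grid, dtype=float)
    if structure is None:
        structure = block_structure(system, grid, tol)

    conditions = []
    delta = np.inf
    all_signs_ok = True
    for block in structure.blocks:
        idx = np.array(block, dtype=int)
        worst_diag = -np.inf      # max diagonal entry (want < 0)
        worst_off = np.inf        # min off-diagonal entry (want >= 0)
        worst_rowsum = -np.inf    # max within-block row sum (want <= -delta)
        for t in grid:
            Bnn = system.B_at(t)[np.ix_(idx, idx)]
            diag = np.diag(Bnn)
            worst_diag = max(worst_diag, float(diag.max()))
            off = Bnn[~np.eye(len(idx), dtype=bool)]
            if off.size:
                worst_off = min(worst_off, float(off.min()))
            worst_rowsum = max(worst_rowsum, float(Bnn.sum(axis=1).max()))
        cond = {
            "block": [i + 1 for i in block],
            "diag_negative": worst_diag < -tol,
            "offdiag_nonnegative": (worst_off >= -tol) if np.isfinite(worst_off) else True,
            "row_sums_dominant": worst_rowsum < -tol,
            "worst_diag": worst_diag,
            "worst_offdiag": None if not np.isfinite(worst_off) else worst_off,
            "worst_row_sum": worst_rowsum,
        }
        conditions.append(cond)
        all_signs_ok &= cond["diag_negative"] and cond["offdiag_nonnegative"]
        delta = min(delta, -worst_rowsum)

    delta = max(0.0, float(delta)) if all_signs_ok else 0.0
    return StabilityReport(
        structure=structure, sample_grid=grid,
        mass_conditions=conditions, delta_estimate=delta)


def check_theorem_age(
    system: CompartmentalSystem,
    sample_grid,
    tol: float = EDGE_TOL,
    report: StabilityReport | None = None,
) -> StabilityReport:
    """Check the extra input/witness conditions for mean-age stability.

    (a) every pool of the first block has s_i(t) >= delta at all sampled
    times; (b) every pool of a later block has some donor pool j in an
    earlier block with b_ij(t) >= delta uniformly (the witness j is
    recorded).  The report carries the largest admissible delta for
    these conditions alongside the row-dominance estimate.
    """
    grid = np.asarray(sample_grid, dtype=float)
    if report is None:
        report = check_theorem_mass(system, grid, tol)
    blocks = report.structure.blocks

    first = np.array(blocks[0], dtype=int)
    s_min = np.inf
    for t in grid:
        s = system.s_at(t)[first]
        s_min = min(s_min, float(s.min()))
    inputs_ok = s_min > tol

    witnesses: dict[int, int | None] = {}
    witness_margin = np.inf
    earlier: list[int] = list(blocks[0])
    for block in blocks[1:]:
        for i in block:
            best_j, best_val = None, -np.inf
            for j in earlier:
                val = min(float(system.B_at(t)[i, j]) for t in grid)
                if val > best_val:
                    best_j, best_val = j, val
            witnesses[i + 1] = None if best_val <= tol else best_j + 1
            if best_val > tol:
                witness_margin = min(witness_margin, best_val)
            else:
                witness_margin = 0.0
        earlier.extend(block)
    witnesses_ok = all(v is not None for v in witnesses.values())

    delta_age = min(max(s_min, 0.0),
                    witness_margin if np.isfinite(witness_margin) else max(s_min, 0.0))
    report.age_conditions = {
        "inputs_ok": inputs_ok,
        "min_first_block_input": s_min,
        "witnesses_ok": witnesses_ok,
        "witnesses": witnesses,
        "delta_estimate": float(delta_age),
    }
    return report


def empirical_decay(
    system: CompartmentalSystem,
    t0: float,
    t1: float,
    n_points: int = 40,
    **solver_options,
) -> tuple[float, float, float]:
    """Fit ||Phi(t, t0)|| <= K exp(-gamma (t - t0)) empirically.

    Computes the spectral norm of the transition operator on a grid and
    least-squares fits log||Phi|| against t over the tail half of the
    grid (skipping transients).  Returns ``(K, gamma, residual)`` with
    gamma > 0 meaning empirically stable; norm growth simply yields
    gamma <= 0.
    """
    if t1 <= t0:
        raise ValueError("empirical decay requires t1 > t0")
    grid = np.linspace(t0, t1, n_points)
    # the norm may decay through many orders of magnitude; keep the
    # error control relative so the tail is not drowned in atol noise
    solver_options.setdefault("rtol", 1e-10)
    solver_options.setdefault("atol", 1e-60)
    Phis = transition_operators(system, t0, grid, **solver_options)
    norms = np.array([np.linalg.norm(P, 2) for P in Phis])
    tail = slice(n_points // 2, None)
    logn = np.log(np.maximum(norms[tail], 1e-300))
    slope, intercept = np.polyfit(grid[tail] - t0, logn, 1)
    resid = float(np.sqrt(np.mean((np.polyval([slope, intercept], grid[tail] - t0) - logn) ** 2)))
    return float(np.exp(intercept)), float(-slope), resid
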