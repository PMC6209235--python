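"""Global hypothesis selection as 0-1 linear programming.

The classical track-oriented MHT selection is a one-to-one program: pick the
set of hypotheses maximising total score subject to no two selected
hypotheses sharing a detection.  Under dense merged detections that
constraint is too brittle — a track that briefly shares a merged detection
is rejected wholesale.  The extended program relaxes it with one adjunctive
binary ``I_ij`` per detection-sharing pair:

    min  sum_n xi_n * C_Tn  +  sum_(i,j) I_ij * C_Iij
    s.t. I_ij >= xi_i + xi_j - 1
         I_ij <= (xi_i + xi_j) / 2
         xi, I in {0, 1}

with ``C_Tn = -K * S(T_n)`` and ``C_Iij = N_ij * C_IN`` while the number of
shared detections ``N_ij`` stays below the tolerance ``N_T``; at or above
``N_T`` the pair is hard-excluded (``xi_i + xi_j <= 1``, the realisation of
the "infinite cost" branch).  With positive pair costs, any optimum has
``I_ij = 1`` exactly when both members are selected, so co-selection of
overlapping tracks is paid for per shared detection instead of forbidden.

Solved exactly with HiGHS via :func:`scipy.optimize.milp`; a brute-force
enumerator is the fallback for small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = [
    "SelectionConfig",
    "SelectionProblem",
    "SelectionResult",
    "pairwise_incompatibility",
    "build_problem",
    "solve",
    "solve_one_to_one",
]


@dataclass
class SelectionConfig:
    """K scales hypothesis scores into costs; C_IN prices one shared
    detection; N_T is the largest tolerated number of shared detections
    before a pair becomes mutually exclusive."""

    k: float = 5.0
    c_in: float = 1.0
    n_t: int = 5
    association: str = "one-to-many"   # or "one-to-one"


@dataclass
class SelectionProblem:
    costs: list                      # C_Tn per hypothesis
    pairs: list = field(default_factory=list)       # (i, j, n_ij, c_ij), 0 < n_ij < N_T
    hard_pairs: list = field(default_factory=list)  # (i, j) with n_ij >= N_T
    all_pairs: list = field(default_factory=list)   # (i, j, n_ij) for every n_ij >= 1

    @property
    def n(self) -> int:
        return len(self.costs)


@dataclass
class SelectionResult:
    selected: list
    objective: float
    status: str = "optimal"


def pairwise_incompatibility(h_i, h_j) -> int:
    """Number of frames where both hypotheses contain the same non-dummy
    detection."""
    lo = max(h_i.birth_frame, h_j.birth_frame)
    hi = min(h_i.last_frame, h_j.last_frame)
    count = 0
    for f in range(lo, hi + 1):
        a, b = h_i.detection_at(f), h_j.detection_at(f)
        if (
            a is not None
            and b is not None
            and not a.is_dummy
            and not b.is_dummy
            and a.detection_id == b.detection_id
        ):
            count += 1
    return count


def build_problem(
    hypotheses: list, scores: list, config: SelectionConfig | None = None
) -> SelectionProblem:
    """Assemble costs and pair structure from scored hypotheses.

    Shared-detection counts are accumulated through a (frame, detection)
    index rather than all-pairs scans, so the cost is proportional to the
    actual overlap structure.
    """
    cfg = config or SelectionConfig()
    costs = [-cfg.k * s for s in scores]
    prob = SelectionProblem(costs=costs)
    occupancy: dict[tuple, list] = {}
    for idx, h in enumerate(hypotheses):
        for det in h.detections:
            if not det.is_dummy:
                occupancy.setdefault((det.frame_index, det.detection_id), []).append(idx)
    shared: dict[tuple, int] = {}
    for members in occupancy.values():
        for i, j in itertools.combinations(members, 2):
            key = (i, j) if i < j else (j, i)
            shared[key] = shared.get(key, 0) + 1
    for (i, j), n_ij in sorted(shared.items()):
        prob.all_pairs.append((i, j, n_ij))
        if n_ij >= cfg.n_t:
            prob.hard_pairs.append((i, j))
        else:
            prob.pairs.append((i, j, n_ij, n_ij * cfg.c_in))
    return prob


def _brute_force(
    costs: list, pair_costs: list, hard_pairs: list
) -> SelectionResult:
    """Exhaustive enumeration over all 2^n selections; lexicographically
    smallest selected index set wins among ties."""
    n = len(costs)
    best: tuple | None = None
    for mask in range(1 << n):
        sel = tuple(i for i in range(n) if mask >> i & 1)
        sset = set(sel)
        if any(i in sset and j in sset for i, j in hard_pairs):
            continue
        obj = sum(costs[i] for i in sel)
        obj += sum(c for i, j, c in pair_costs if i in sset and j in sset)
        if best is None or (obj, sel) < best:
            best = (obj, sel)
    assert best is not None  # the empty selection is always feasible
    return SelectionResult(selected=list(best[1]), objective=best[0])


def _solve_milp(
    costs: list, pair_costs: list, hard_pairs: list
) -> SelectionResult | None:
    n = len(costs)
    m = len(pair_costs)
    c = np.concatenate([np.asarray(costs, dtype=float), [pc for *_, pc in pair_costs]])
    rows, constraints = [], []
    a_rows = []
    lb, ub = [], []
    for k, (i, j, _pc) in enumerate(pair_costs):
        # xi_i + xi_j - I_ij <= 1   (forces I=1 when both selected)
        row = np.zeros(n + m)
        row[i] += 1
        row[j] += 1
        row[n + k] = -1
        a_rows.append(row)
        lb.append(-np.inf)
        ub.append(1.0)
        # 2*I_ij - xi_i - xi_j <= 0 (forces I=0 unless both selected)
        row = np.zeros(n + m)
        row[i] -= 1
        row[j] -= 1
        row[n + k] = 2
        a_rows.append(row)
        lb.append(-np.inf)
        ub.append(0.0)
    for i, j in hard_pairs:
        row = np.zeros(n + m)
        row[i] = 1
        row[j] = 1
        a_rows.append(row)
        lb.append(-np.inf)
        ub.append(1.0)
    if a_rows:
        constraints = [LinearConstraint(sparse.csr_matrix(np.array(a_rows)), lb, ub)]
    res = milp(
        c=c,
        constraints=constraints,
        integrality=np.ones(n + m),
        bounds=Bounds(0, 1),
    )
    if not res.success:
        return None
    x = np.round(res.x[:n]).astype(int)
    selected = [i for i in range(n) if x[i] == 1]
    sset = set(selected)
    obj = sum(costs[i] for i in selected) + sum(
        pc for i, j, pc in pair_costs if i in sset and j in sset
    )
    return SelectionResult(selected=selected, objective=float(obj))


def solve(problem: SelectionProblem) -> SelectionResult:
    """Exact optimum of the extended (one-to-many) program."""
    pair_costs = [(i, j, c) for i, j, _n, c in problem.pairs]
    if problem.n == 0:
        return SelectionResult(selected=[], objective=0.0)
    result = _solve_milp(problem.costs, pair_costs, problem.hard_pairs)
    if result is None:
        if problem.n <= 20:
            return _brute_force(problem.costs, pair_costs, problem.hard_pairs)
        return SelectionResult(selected=[], objective=0.0, status="failed")
    return result


def solve_one_to_one(problem: SelectionProblem) -> SelectionResult:
    """Classical formulation: every detection-sharing pair is mutually
    exclusive (xi_i + xi_j <= 1); no pair costs."""
    if problem.n == 0:
        return SelectionResult(selected=[], objective=0.0)
    hard = [(i, j) for i, j, _n in problem.all_pairs]
    result = _solve_milp(problem.costs, [], hard)
    if result is None:
        if problem.n <= 20:
            return _brute_force(problem.costs, [], hard)
        return SelectionResult(selected=[], objective=0.0, status="failed")
    return result


def dump_lp(problem: SelectionProblem, path: str) -> None:
    """Write the extended program in LP text format for auditing."""
    lines = ["Minimize", " obj: " + " + ".join(
        f"{c:+.6g} x{i}" for i, c in enumerate(problem.costs)
    ) + "".join(f" {c:+.6g} I{i}_{j}" for i, j, _n, c in problem.pairs)]
    lines.append("Subject To")
    for i, j, _n, _c in problem.pairs:
        lines.append(f" link1_{i}_{j}: x{i} + x{j} - I{i}_{j} <= 1")
        lines.append(f" link2_{i}_{j}: 2 I{i}_{j} - x{i} - x{j} <= 0")
    for i, j in problem.hard_pairs:
        lines.append(f" excl_{i}_{j}: x{i} + x{j} <= 1")
    lines.append("Binary")
    lines.append(" " + " ".join(f"x{i}" for i in range(problem.n)))
    if problem.pairs:
        lines.append(" " + " ".join(f"I{i}_{j}" for i, j, _n, _c in problem.pairs))
    lines.append("End")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
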