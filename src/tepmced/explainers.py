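"""Shapley attribution backends.

All backends attribute the cancer-class output of a fitted classifier with
respect to an interventional background: the value of a feature coalition S
for sample x is the expected model output when features in S take x's
values and the rest are drawn from the background rows.

Backends:

- ``linear_shap`` — closed form for linear models: phi_j = beta_j (x_j - mu_j)
  in the margin (log-odds) space; exact and additive.
- ``TreeEnsembleExplainer`` — exact interventional Shapley values for tree
  ensembles. For a fixed (x, z) pair each leaf is reached iff the coalition
  contains every path feature where x and z take different branches on x's
  side (set A) and excludes every such feature on z's side (set B); the leaf
  then contributes with the unanimity-with-blockers weights
  (|A|-1)! |B|! / (|A|+|B|)! (positive for A, negative for B). Averaging
  over background rows gives the exact interventional Shapley value.
  Numba-compiled; exact and additive.
- ``kernel_shap`` — model-agnostic weighted-least-squares estimator with the
  efficiency constraint built in (so attributions always sum to
  f(x) - base). Enumerates all coalitions when feasible, otherwise includes
  all size-1 and size-(p-1) coalitions and samples the rest proportionally
  to the Shapley kernel.
- ``integrated_gradients`` — path-integral gradient attribution for the
  neural models, averaged over background references; additive up to
  discretization error.
"""

from __future__ import annotations

import json
import math

import numpy as np
from numba import njit


# ---------------------------------------------------------------------------
# linear backend
# ---------------------------------------------------------------------------

def linear_shap(beta: np.ndarray, intercept: float, X: np.ndarray, background: np.ndarray
                ) -> tuple[np.ndarray, float]:
    """Closed-form Shapley values of a linear margin model.

    Returns (phi with shape (n, p), base_value = beta . mu + intercept).
    """
    beta = np.asarray(beta, dtype=float).ravel()
    mu = np.asarray(background, dtype=float).mean(axis=0)
    phi = (np.asarray(X, dtype=float) - mu) * beta[None, :]
    base = float(beta @ mu + intercept)
    return phi, base


# ---------------------------------------------------------------------------
# exact interventional tree backend
# ---------------------------------------------------------------------------

@njit(cache=False)
def _tree_shap_kernel(X, Z, feat, thr, left, right, value, offsets, strict, phi):  # pragma: no cover
    n, p = X.shape
    m = Z.shape[0]
    n_trees = offsets.shape[0] - 1
    max_depth = 80
    path_feat = np.empty(max_depth, np.int64)
    path_role = np.empty(max_depth, np.int64)  # 1: x-side (in A), 2: z-side (in B)
    stack_node = np.empty(4 * max_depth, np.int64)
    stack_len = np.empty(4 * max_depth, np.int64)
    stack_feat = np.empty(4 * max_depth, np.int64)
    stack_role = np.empty(4 * max_depth, np.int64)

    for i in range(n):
        for zi in range(m):
            for t in range(n_trees):
                root = offsets[t]
                sp = 0
                stack_node[sp] = root
                stack_len[sp] = 0
                stack_feat[sp] = -1
                stack_role[sp] = 0
                sp += 1
                while sp > 0:
                    sp -= 1
                    node = stack_node[sp]
                    plen = stack_len[sp]
                    if stack_feat[sp] >= 0:
                        path_feat[plen - 1] = stack_feat[sp]
                        path_role[plen - 1] = stack_role[sp]
                    contradict = False
                    while feat[node] >= 0:
                        f = feat[node]
                        tv = thr[node]
                        if strict:
                            xg = X[i, f] < tv
                            zg = Z[zi, f] < tv
                        else:
                            xg = X[i, f] <= tv
                            zg = Z[zi, f] <= tv
                        if xg == zg:
                            node = left[node] if xg else right[node]
                            continue
                        # x and z branch apart on feature f
                        existing = 0
                        for q in range(plen):
                            if path_feat[q] == f:
                                existing = path_role[q]
                                break
                        if existing == 1:
                            node = left[node] if xg else right[node]
                        elif existing == 2:
                            node = left[node] if zg else right[node]
                        else:
                            if plen + 1 >= max_depth:
                                contradict = True  # path too deep; should not happen
                                break
                            # push z-side continuation
                            stack_node[sp] = left[node] if zg else right[node]
                            stack_len[sp] = plen + 1
                            stack_feat[sp] = f
                            stack_role[sp] = 2
                            sp += 1
                            # continue inline on x side
                            path_feat[plen] = f
                            path_role[plen] = 1
                            plen += 1
                            node = left[node] if xg else right[node]
                    if contradict:
                        continue
                    # leaf reached
                    a = 0
                    b = 0
                    for q in range(plen):
                        if path_role[q] == 1:
                            a += 1
                        else:
                            b += 1
                    if a + b == 0:
                        continue  # contributes equally to v(S) for all S
                    val = value[node]
                    # (a-1)! b! / (a+b)!  and  a! (b-1)! / (a+b)!
                    if a > 0:
                        wa = math.exp(math.lgamma(a) + math.lgamma(b + 1.0) - math.lgamma(a + b + 1.0))
                    else:
                        wa = 0.0
                    if b > 0:
                        wb = math.exp(math.lgamma(a + 1.0) + math.lgamma(b) - math.lgamma(a + b + 1.0))
                    else:
                        wb = 0.0
                    for q in range(plen):
                        if path_role[q] == 1:
                            phi[i, path_feat[q]] += val * wa
                        else:
                            phi[i, path_feat[q]] -= val * wb
    for i in range(n):
        for j in range(p):
            phi[i, j] /= m


class TreeEnsembleExplainer:
    """Exact interventional Shapley values for additive tree ensembles.

    The ensemble is a flat array representation: per node a split feature
    (-1 for leaves), threshold, child indices and a leaf contribution to the
    (additive) model output. ``strict`` selects ``x < t`` (gradient-boosting
    convention) vs ``x <= t`` split semantics.
    """

    def __init__(self, feat, thr, left, right, value, offsets, intercept: float = 0.0,
                 strict: bool = False) -> None:
        self.feat = np.asarray(feat, dtype=np.int64)
        self.thr = np.asarray(thr, dtype=np.float64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.value = np.asarray(value, dtype=np.float64)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.intercept = float(intercept)
        self.strict = bool(strict)

    # ---- constructors -----------------------------------------------------
    @classmethod
    def from_sklearn(cls, model) -> "TreeEnsembleExplainer":
        """From DecisionTreeClassifier or RandomForestClassifier; leaf values
        are class-1 probabilities averaged across trees, so the explained
        output is ``predict_proba[:, 1]``."""
        trees = getattr(model, "estimators_", [model])
        feat, thr, left, right, value, offsets = [], [], [], [], [], [0]
        n_trees = len(trees)
        for est in trees:
            tr = est.tree_
            base = offsets[-1]
            feat.extend(tr.feature.tolist())
            thr.extend(tr.threshold.tolist())
            left.extend([(c + base) if c >= 0 else -1 for c in tr.children_left])
            right.extend([(c + base) if c >= 0 else -1 for c in tr.children_right])
            v = tr.value[:, 0, :]
            with np.errstate(invalid="ignore"):
                p1 = v[:, 1] / v.sum(axis=1) if v.shape[1] == 2 else v[:, 0]
            value.extend((p1 / n_trees).tolist())
            offsets.append(base + tr.node_count)
        return cls(feat, thr, left, right, value, offsets, intercept=0.0, strict=False)

    @classmethod
    def from_xgboost(cls, model, reference_row: np.ndarray) -> "TreeEnsembleExplainer":
        """From a fitted XGBClassifier; the explained output is the margin
        (log-odds). The additive intercept is recovered numerically from one
        reference row."""
        dumps = model.get_booster().get_dump(dump_format="json")
        feat, thr, left, right, value, offsets = [], [], [], [], [], [0]

        def walk(node, store):
            idx = len(store["feat"])
            store["feat"].append(-1)
            store["thr"].append(0.0)
            store["left"].append(-1)
            store["right"].append(-1)
            store["value"].append(0.0)
            if "leaf" in node:
                store["value"][idx] = float(node["leaf"])
                return idx
            f = node["split"]
            store["feat"][idx] = int(f[1:]) if isinstance(f, str) and f.startswith("f") else int(f)
            # thresholds are float32 in the engine; snap the parsed decimal
            # back to binary32 so boundary comparisons match bit-for-bit
            store["thr"][idx] = float(np.float32(node["split_condition"]))
            kids = {c["nodeid"]: c for c in node["children"]}
            store["left"][idx] = walk(kids[node["yes"]], store)
            store["right"][idx] = walk(kids[node["no"]], store)
            return idx

        for d in dumps:
            store = {"feat": [], "thr": [], "left": [], "right": [], "value": []}
            walk(json.loads(d), store)
            base = offsets[-1]
            feat.extend(store["feat"])
            thr.extend(store["thr"])
            left.extend([(c + base) if c >= 0 else -1 for c in store["left"]])
            right.extend([(c + base) if c >= 0 else -1 for c in store["right"]])
            value.extend(store["value"])
            offsets.append(base + len(store["feat"]))

        exp = cls(feat, thr, left, right, value, offsets, intercept=0.0, strict=True)
        ref = np.asarray(reference_row, dtype=float).reshape(1, -1)
        margin = float(model.predict(ref, output_margin=True)[0])
        exp.intercept = margin - exp.evaluate(ref)[0]
        return exp

    # ---- evaluation -------------------------------------------------------
    def _prep(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.strict:
            # gradient-boosting engines compare in float32; replicate exactly
            X = X.astype(np.float32).astype(np.float64)
        return X

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Additive model output (sum of leaf values + intercept) per row."""
        X = self._prep(X)
        out = np.full(X.shape[0], self.intercept, dtype=float)
        for t in range(self.offsets.size - 1):
            node = np.full(X.shape[0], self.offsets[t])
            active = np.ones(X.shape[0], dtype=bool)
            while True:
                is_split = self.feat[node] >= 0
                if not is_split.any():
                    break
                f = self.feat[node]
                rows = np.flatnonzero(is_split)
                xv = X[rows, f[rows]]
                if self.strict:
                    go_left = xv < self.thr[node[rows]]
                else:
                    go_left = xv <= self.thr[node[rows]]
                node[rows] = np.where(go_left, self.left[node[rows]], self.right[node[rows]])
            out += self.value[node]
        return out

    def shap_values(self, X: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, float]:
        """Exact interventional Shapley values; returns (phi, base_value)."""
        X = np.ascontiguousarray(self._prep(X))
        Z = np.ascontiguousarray(self._prep(background))
        phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
        _tree_shap_kernel(
            X, Z, self.feat, self.thr, self.left, self.right, self.value,
            self.offsets, self.strict, phi,
        )
        base = float(self.evaluate(Z).mean())
        return phi, base


# ---------------------------------------------------------------------------
# kernel backend
# ---------------------------------------------------------------------------

def _shapley_kernel_weight(p: int, s: int) -> float:
    return (p - 1) / (math.comb(p, s) * s * (p - s))


def kernel_shap(
    f,
    X: np.ndarray,
    background: np.ndarray,
    n_coalitions: int = 2048,
    seed: int = 0,
    batch_rows: int = 200_000,
) -> tuple[np.ndarray, float]:
    """Shapley values via the weighted-least-squares characterization.

    ``f`` maps an (n, p) array to an (n,) output. v(S) is the background
    average of f on composites; the efficiency constraint
    sum(phi) = f(x) - base is enforced exactly by substitution. All
    coalitions are enumerated when 2^p - 2 fits the budget; otherwise all
    singleton and leave-one-out coalitions are included and the remainder
    sampled proportionally to the Shapley kernel.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(background, dtype=float)
    n, p = X.shape
    m = Z.shape[0]
    rng = np.random.default_rng(seed)

    if p == 1:
        base = float(np.mean(f(Z)))
        return (f(X) - base).reshape(-1, 1), base

    # coalition masks and regression weights
    if p <= 24 and 2**p - 2 <= n_coalitions:
        masks = np.zeros((2**p - 2, p), dtype=bool)
        weights = np.empty(2**p - 2)
        r = 0
        for code in range(1, 2**p - 1):
            mk = np.array([(code >> j) & 1 for j in range(p)], dtype=bool)
            masks[r] = mk
            weights[r] = _shapley_kernel_weight(p, int(mk.sum()))
            r += 1
    else:
        rows = []
        for j in range(p):
            mk = np.zeros(p, dtype=bool)
            mk[j] = True
            rows.append(mk.copy())
            rows.append(~mk)
        n_extra = max(n_coalitions - len(rows), 0)
        if p > 3 and n_extra:
            sizes = np.arange(2, p - 1)
            size_w = np.array([_shapley_kernel_weight(p, int(s)) * math.comb(p, int(s)) for s in sizes])
            size_w = size_w / size_w.sum()
            drawn_sizes = rng.choice(sizes, size=n_extra, p=size_w)
            for s in drawn_sizes:
                mk = np.zeros(p, dtype=bool)
                mk[rng.choice(p, size=int(s), replace=False)] = True
                rows.append(mk)
        masks = np.asarray(rows)
        weights = np.ones(masks.shape[0])
        for j in range(2 * p):  # enumerated coalitions keep their exact kernel weight
            weights[j] = _shapley_kernel_weight(p, int(masks[j].sum()))
        n_sampled = masks.shape[0] - 2 * p
        if n_sampled > 0:
            # total kernel mass of the sampled sizes, spread evenly (rows were
            # drawn proportionally to the kernel)
            mass = sum(
                _shapley_kernel_weight(p, s) * math.comb(p, s) for s in range(2, p - 1)
            )
            weights[2 * p:] = mass / n_sampled

    base = float(np.mean(f(Z)))
    fx = np.asarray(f(X), dtype=float)

    # evaluate v(S) for every (sample, coalition), batching model calls
    n_s = masks.shape[0]
    phi = np.zeros((n, p))
    sqrt_w = np.sqrt(weights)
    for i in range(n):
        vs = np.empty(n_s)
        row = X[i]
        # composite points: for each coalition, m background completions
        done = 0
        per_batch = max(1, batch_rows // m)
        while done < n_s:
            hi = min(done + per_batch, n_s)
            blk = masks[done:hi]
            comp = np.repeat(Z[None, :, :], hi - done, axis=0)  # (b, m, p)
            comp[:, :, :] = np.where(blk[:, None, :], row[None, None, :], comp)
            vals = np.asarray(f(comp.reshape(-1, p)), dtype=float).reshape(hi - done, m)
            vs[done:hi] = vals.mean(axis=1)
            done = hi
        y = vs - base
        delta = fx[i] - base
        A = masks.astype(float)
        # eliminate phi_{p-1} through the efficiency constraint
        Ared = A[:, :-1] - A[:, -1:]
        yred = y - A[:, -1] * delta
        sol, *_ = np.linalg.lstsq(Ared * sqrt_w[:, None], yred * sqrt_w, rcond=None)
        phi[i, :-1] = sol
        phi[i, -1] = delta - sol.sum()
    return phi, base


# ---------------------------------------------------------------------------
# gradient backend
# ---------------------------------------------------------------------------

def integrated_gradients(
    value_and_grad,
    X: np.ndarray,
    background: np.ndarray,
    n_steps: int = 32,
    max_background: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Path-integral gradients averaged over background references.

    ``value_and_grad`` is a pair (f, grad_f) of callables on (n, p) arrays.
    phi_i(x) = E_z[(x_i - z_i) * mean_t grad_i(z + alpha_t (x - z))] with
    alpha_t at step midpoints. Additivity holds up to discretization error.
    """
    f, grad_f = value_and_grad
    X = np.asarray(X, dtype=float)
    Z = np.asarray(background, dtype=float)
    if Z.shape[0] > max_background:
        rng = np.random.default_rng(seed)
        Z = Z[rng.choice(Z.shape[0], size=max_background, replace=False)]
    n, p = X.shape
    m = Z.shape[0]
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    phi = np.zeros((n, p))
    for i in range(n):
        diff = X[i][None, :] - Z  # (m, p)
        grads = np.zeros((m, p))
        for a in alphas:
            pts = Z + a * diff
            grads += grad_f(pts)
        grads /= n_steps
        phi[i] = (diff * grads).mean(axis=0)
    base = float(np.mean(f(Z)))
    return phi, base
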