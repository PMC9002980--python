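"""Feature-subset selection.

Two routes are provided:

* :func:`fixed_paper_subset` — the published operating point: {IEMG, RMS,
  AIF} on all four channels, 12 columns.  This is the default pipeline mode
  and the reproducibility anchor.
* :func:`mbtga_select` — a binary tree-growth metaheuristic wrapper search.
  The original "modified" operators are not published, so this is a standard
  binary tree-growth scheme: the population of candidate masks is sorted by
  fitness each generation; the best N1 trees undergo greedy single-bit-flip
  local search with a shrinking flip budget, the next N2 are drawn toward a
  random convex combination of the two best, N3 fresh random trees are
  injected and the worst N4 are replaced.  Continuous tree positions in
  [0, 1]^d are binarised through an S- or V-shaped transfer function.
  Fitness = alpha * (inner cross-validated error of a cheap k-NN classifier
  on the masked features) + (1 - alpha) * (bits set / total), minimised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .core_io import CHANNEL_NAMES, ValidationError, logger
from .features import FeatureMatrix, column_name

PAPER_SUBSET_FEATURES = ("IEMG", "RMS", "AIF")


@dataclass
class FeatureMask:
    """Binary inclusion vector over named feature columns."""

    mask: np.ndarray            # bool, one entry per column
    columns: list[str]
    provenance: str = "none"    # none | fixed_paper_subset | mbtga

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != len(self.columns):
            raise ValidationError("mask length does not match column count")
        if not self.mask.any():
            raise ValidationError("mask must select at least one column")

    @property
    def selected(self) -> list[str]:
        return [c for c, b in zip(self.columns, self.mask) if b]

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps({
            "provenance": self.provenance,
            "columns": self.columns,
            "mask": [int(b) for b in self.mask],
            "selected": self.selected,
        }, indent=2))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureMask":
        d = json.loads(Path(path).read_text())
        return cls(mask=np.array(d["mask"], dtype=bool), columns=d["columns"],
                   provenance=d.get("provenance", "none"))


def fixed_paper_subset(columns: list[str]) -> FeatureMask:
    """Mask selecting {IEMG, RMS, AIF} on every channel (12 columns).

    Invariant to column order; errors if any expected column is absent.
    """
    wanted = {column_name(ch, f) for ch in CHANNEL_NAMES for f in PAPER_SUBSET_FEATURES}
    missing = wanted - set(columns)
    if missing:
        raise ValidationError(f"columns missing for fixed subset: {sorted(missing)}")
    mask = np.array([c in wanted for c in columns], dtype=bool)
    return FeatureMask(mask=mask, columns=list(columns),
                       provenance="fixed_paper_subset")


def apply_mask(fm: FeatureMatrix, m: FeatureMask) -> FeatureMatrix:
    """Column-subset of a feature matrix, preserving ids and labels."""
    if len(m.mask) != len(fm.columns):
        raise ValidationError(
            f"mask length {len(m.mask)} != column count {len(fm.columns)}")
    return FeatureMatrix(data=fm.data.loc[:, m.mask], labels=fm.labels)


# ---------------------------------------------------------------------------
# binary tree-growth search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TgaParams:
    population: int = 20
    n1: int = 6          # best trees: local search
    n2: int = 6          # trees moved toward the two best
    n3: int = 4          # fresh random trees
    n4: int = 4          # worst trees replaced
    iterations: int = 50
    alpha: float = 0.99  # weight of the error term vs subset size
    transfer: str = "s_shaped"
    inner_neighbors: int = 5
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 + self.n2 + self.n3 > self.population:
            raise ValidationError("N1 + N2 + N3 must be <= population")
        if not (0 < self.alpha <= 1):
            raise ValidationError("alpha must be in (0, 1]")
        if self.transfer not in ("s_shaped", "v_shaped"):
            raise ValidationError("transfer must be s_shaped or v_shaped")
        if self.iterations < 1:
            raise ValidationError("iteration budget must be >= 1")


def _transfer(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "s_shaped":
        return 1.0 / (1.0 + np.exp(-10.0 * (x - 0.5)))
    return np.abs(np.tanh(4.0 * (x - 0.5)))


class _FitnessCache:
    """Cross-validated k-NN error of a mask, memoised by mask bytes."""

    def __init__(self, fm: FeatureMatrix, params: TgaParams):
        X = fm.data.to_numpy()
        # z-score so every column contributes comparably to the distances
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        self.X = (X - X.mean(axis=0)) / sd
        self.y = fm.labels.to_numpy()
        self.alpha = params.alpha
        self.d = X.shape[1]
        self.k = params.inner_neighbors
        skf = StratifiedKFold(n_splits=params.inner_folds, shuffle=True,
                              random_state=params.seed)
        self.splits = list(skf.split(self.X, self.y))
        self.cache: dict[bytes, float] = {}
        self.evaluations = 0

    def error(self, mask: np.ndarray) -> float:
        Xm = self.X[:, mask]
        errs = []
        for tr, te in self.splits:
            clf = KNeighborsClassifier(n_neighbors=min(self.k, len(tr)))
            clf.fit(Xm[tr], self.y[tr])
            errs.append(np.mean(clf.predict(Xm[te]) != self.y[te]))
        return float(np.mean(errs))

    def __call__(self, mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in self.cache:
            self.evaluations += 1
            self.cache[key] = (self.alpha * self.error(mask)
                               + (1 - self.alpha) * mask.sum() / self.d)
        return self.cache[key]


def _binarize(pos: np.ndarray, rng: np.random.Generator, kind: str) -> np.ndarray:
    mask = rng.random(pos.shape) < _transfer(pos, kind)
    return mask


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(len(mask))] = True
    return mask


def mbtga_select(fm: FeatureMatrix, params: TgaParams | None = None
                 ) -> tuple[FeatureMask, list[float]]:
    """Evolve a population of binary masks; returns the best mask and the
    per-iteration best-fitness trace (non-increasing by elitism).
    """
    params = params or TgaParams()
    y = fm.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("mbtga_select needs at least 2 classes")
    rng = np.random.default_rng(params.seed)
    fitness = _FitnessCache(fm, params)
    d = fitness.d
    pop, kind = params.population, params.transfer

    positions = rng.random((pop, d))
    masks = np.array([_repair(_binarize(p, rng, kind), rng) for p in positions])
    fits = np.array([fitness(m) for m in masks])

    best_mask = masks[np.argmin(fits)].copy()
    best_fit = float(np.min(fits))
    trace: list[float] = []

    for t in range(params.iterations):
        order = np.argsort(fits, kind="stable")
        positions, masks, fits = positions[order], masks[order], fits[order]

        # N1 best: greedy single-bit-flip local search, shrinking budget
        flips = max(1, int(round(0.1 * d * (1 - t / params.iterations))))
        for i in range(params.n1):
            for _ in range(flips):
                j = int(rng.integers(d))
                cand = masks[i].copy()
                cand[j] = ~cand[j]
                cand = _repair(cand, rng)
                f = fitness(cand)
                if f < fits[i]:
                    masks[i], fits[i] = cand, f
                    positions[i, j] = 0.9 if cand[j] else 0.1

        # N2: move toward a random convex combination of the two best
        b1, b2 = positions[0], positions[1]
        for i in range(params.n1, params.n1 + params.n2):
            lam = rng.random(d)
            positions[i] = lam * b1 + (1 - lam) * b2
            masks[i] = _repair(_binarize(positions[i], rng, kind), rng)
            fits[i] = fitness(masks[i])

        # N3 fresh random trees and N4 worst replaced
        refresh = list(range(params.n1 + params.n2, params.n1 + params.n2 + params.n3))
        refresh += list(range(pop - params.n4, pop))
        for i in set(refresh):
            positions[i] = rng.random(d)
            masks[i] = _repair(_binarize(positions[i], rng, kind), rng)
            fits[i] = fitness(masks[i])

        i_best = int(np.argmin(fits))
        if fits[i_best] < best_fit:
            best_fit, best_mask = float(fits[i_best]), masks[i_best].copy()
        trace.append(best_fit)

    logger.info("mbtga: best fitness %.4f, %d/%d columns, %d evaluations",
                best_fit, int(best_mask.sum()), d, fitness.evaluations)
    return (FeatureMask(mask=best_mask, columns=fm.columns, provenance="mbtga"),
            trace)
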