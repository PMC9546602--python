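"""The Quad multinomial processing tree model.

The Quad model decomposes two-key categorization performance into four
latent processes: activation of an evaluative association (AC), detection
of the correct response (D), overcoming bias (OB; detection overriding an
activated conflicting association), and guessing (G; a bias toward the key
currently assigned to "pleasant").  Two AC parameters are estimated, one
per evaluative association, so the parameter vector is
``(ac_a, ac_b, d_detect, ob, g)``.

A :class:`QuadSpecification` wires the tree to the 8 (stimulus category x
pairing) cells: which association is active in a cell and whether the
activated association pushes the correct or the incorrect key there.  The
*outgroup-bias* specification assigns ``ac_a`` to the
outgroup-with-pleasant association and ``ac_b`` to the
ingroup-with-unpleasant association; the *ingroup-bias* specification
mirrors this (``ac_a`` = ingroup-pleasant, ``ac_b`` = outgroup-unpleasant).
An association (group, valence) pushes toward the correct key exactly in
the pairing where its group and valence share a response key, and toward
the incorrect key in the other pairing.

Cell probabilities exist both as an explicit path enumeration (for audit
and testing) and as closed forms (for fitting); the two must agree to
machine precision.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .iat_data import CELLS, Pairing, ResponseCountTable, StimulusCategory

__all__ = [
    "BiasDirection",
    "ActivationMap",
    "QuadParameters",
    "QuadSpecification",
    "CellProbability",
    "PathTerm",
    "TreePath",
    "enumerate_paths",
    "cell_probabilities",
    "cell_probability_array",
    "log_likelihood",
    "simulate_counts",
    "export_equations",
    "PARAM_NAMES",
]

PARAM_NAMES = ("ac_a", "ac_b", "d_detect", "ob", "g")


class BiasDirection(str, enum.Enum):
    OUTGROUP_BIAS = "outgroup_bias"
    INGROUP_BIAS = "ingroup_bias"


class ActivationMap(str, enum.Enum):
    """Which cells each association is active in.

    ``FACES_AND_WORDS`` (default): an association is active on its target
    group's face trials and on its own valence's word trials, in both
    pairings.  ``FACES_ONLY``: active on face trials only; word cells
    reduce to detection plus guessing.
    """

    FACES_AND_WORDS = "faces_and_words"
    FACES_ONLY = "faces_only"


@dataclass(frozen=True)
class QuadParameters:
    ac_a: float
    ac_b: float
    d_detect: float
    ob: float
    g: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "QuadParameters":
        return cls(*(float(x) for x in arr))


_PLEASANT = "pleasant"
_UNPLEASANT = "unpleasant"
_INGROUP = "ingroup"
_OUTGROUP = "outgroup"

_FACE_GROUP = {
    StimulusCategory.INGROUP_TARGET: _INGROUP,
    StimulusCategory.OUTGROUP_TARGET: _OUTGROUP,
}
_WORD_VALENCE = {
    StimulusCategory.PLEASANT_WORD: _PLEASANT,
    StimulusCategory.UNPLEASANT_WORD: _UNPLEASANT,
}


def _shares_key(group: str, valence: str, pairing: Pairing) -> bool:
    """Does this (group, valence) pair sit on one response key in `pairing`?"""
    if pairing is Pairing.INGROUP_PLEASANT:
        return (group == _INGROUP) == (valence == _PLEASANT)
    return (group == _OUTGROUP) == (valence == _PLEASANT)


@dataclass(frozen=True)
class CellWiring:
    """Resolved tree wiring for one cell."""

    ac_index: int  # 0 = ac_a, 1 = ac_b, -1 = no association active
    push_correct: bool  # does the activated association push the correct key?
    pleasant_correct: bool  # is the correct key the pleasant-assigned key?


@dataclass(frozen=True)
class QuadSpecification:
    bias_direction: BiasDirection = BiasDirection.OUTGROUP_BIAS
    activation_map: ActivationMap = ActivationMap.FACES_AND_WORDS

    @property
    def ac_roles(self) -> dict[str, tuple[str, str]]:
        """(group, valence) of each association parameter."""
        if self.bias_direction is BiasDirection.OUTGROUP_BIAS:
            return {"ac_a": (_OUTGROUP, _PLEASANT), "ac_b": (_INGROUP, _UNPLEASANT)}
        return {"ac_a": (_INGROUP, _PLEASANT), "ac_b": (_OUTGROUP, _UNPLEASANT)}

    def wiring(self, cell: tuple[StimulusCategory, Pairing]) -> CellWiring:
        category, pairing = cell
        roles = self.ac_roles
        ac_index = -1
        if category in _FACE_GROUP:
            group = _FACE_GROUP[category]
            for i, name in enumerate(("ac_a", "ac_b")):
                if roles[name][0] == group:
                    ac_index = i
            pleasant_correct = _shares_key(group, _PLEASANT, pairing)
        else:
            valence = _WORD_VALENCE[category]
            if self.activation_map is ActivationMap.FACES_AND_WORDS:
                for i, name in enumerate(("ac_a", "ac_b")):
                    if roles[name][1] == valence:
                        ac_index = i
            pleasant_correct = valence == _PLEASANT

        if ac_index >= 0:
            group, valence = roles[("ac_a", "ac_b")[ac_index]]
            push_correct = _shares_key(group, valence, pairing)
        else:
            push_correct = True  # unused
        return CellWiring(ac_index, push_correct, pleasant_correct)

    def wiring_table(self) -> list[CellWiring]:
        return [self.wiring(cell) for cell in CELLS]


_WIRING_CACHE: dict["QuadSpecification", list[CellWiring]] = {}


@dataclass(frozen=True)
class CellProbability:
    cell: tuple[StimulusCategory, Pairing]
    p_correct: float
    p_incorrect: float


@dataclass(frozen=True)
class PathTerm:
    """One multiplicative factor of a path probability.

    ``symbol`` is a parameter name or the per-cell guessing symbol
    ``"g_cell"``; ``complement`` selects ``1 - value``.
    """

    symbol: str
    complement: bool = False

    def __str__(self) -> str:
        return f"(1 - {self.symbol})" if self.complement else self.symbol

    def value(self, params: QuadParameters, g_cell: float) -> float:
        v = g_cell if self.symbol == "g_cell" else getattr(params, self.symbol)
        return 1.0 - v if self.complement else v


@dataclass(frozen=True)
class TreePath:
    terms: tuple[PathTerm, ...]
    outcome: str  # "correct" | "incorrect"

    def probability(self, params: QuadParameters, g_cell: float) -> float:
        return math.prod(t.value(params, g_cell) for t in self.terms)

    def __str__(self) -> str:
        return " * ".join(str(t) for t in self.terms)


def _T(symbol: str, complement: bool = False) -> PathTerm:
    return PathTerm(symbol, complement)


def enumerate_paths(
    spec: QuadSpecification, cell: tuple[StimulusCategory, Pairing]
) -> list[TreePath]:
    """All root-to-leaf paths of the processing tree for one cell.

    The tree is conditional: OB is reached only when an activated
    association conflicts with successful detection; guessing is reached
    only when no association is active and detection fails.
    """
    w = spec.wiring(cell)
    paths: list[TreePath] = []
    if w.ac_index >= 0:
        ac = PARAM_NAMES[w.ac_index]
        if w.push_correct:
            paths.append(TreePath((_T(ac), _T("d_detect")), "correct"))
            paths.append(TreePath((_T(ac), _T("d_detect", True)), "correct"))
        else:
            paths.append(TreePath((_T(ac), _T("d_detect"), _T("ob")), "correct"))
            paths.append(
                TreePath((_T(ac), _T("d_detect"), _T("ob", True)), "incorrect")
            )
            paths.append(TreePath((_T(ac), _T("d_detect", True)), "incorrect"))
        paths.append(TreePath((_T(ac, True), _T("d_detect")), "correct"))
        paths.append(
            TreePath((_T(ac, True), _T("d_detect", True), _T("g_cell")), "correct")
        )
        paths.append(
            TreePath(
                (_T(ac, True), _T("d_detect", True), _T("g_cell", True)), "incorrect"
            )
        )
    else:
        paths.append(TreePath((_T("d_detect"),), "correct"))
        paths.append(TreePath((_T("d_detect", True), _T("g_cell")), "correct"))
        paths.append(
            TreePath((_T("d_detect", True), _T("g_cell", True)), "incorrect")
        )
    return paths


def _g_cell(params_g: float, pleasant_correct: bool) -> float:
    return params_g if pleasant_correct else 1.0 - params_g


def cell_probability_array(theta: np.ndarray, spec: QuadSpecification) -> np.ndarray:
    """Closed-form p_correct for the 8 cells, vectorized over parameter rows.

    ``theta`` has shape ``(..., 5)`` ordered as :data:`PARAM_NAMES`;
    returns shape ``(..., 8)`` in canonical :data:`CELLS` order.
    """
    theta = np.asarray(theta, dtype=float)
    ac_a, ac_b, d, ob, g = (theta[..., i] for i in range(5))
    out = np.empty(theta.shape[:-1] + (8,), dtype=float)
    wirings = _WIRING_CACHE.get(spec)
    if wirings is None:
        wirings = _WIRING_CACHE[spec] = spec.wiring_table()
    for j, wiring in enumerate(wirings):
        gc = g if wiring.pleasant_correct else 1.0 - g
        base = d + (1.0 - d) * gc  # detection-plus-guessing, no association
        if wiring.ac_index < 0:
            p = base
        else:
            ac = ac_a if wiring.ac_index == 0 else ac_b
            if wiring.push_correct:
                p = ac + (1.0 - ac) * base
            else:
                p = ac * d * ob + (1.0 - ac) * base
        out[..., j] = p
    return out


def cell_probabilities(
    params: QuadParameters, spec: QuadSpecification
) -> list[CellProbability]:
    """Closed-form correct/incorrect probabilities for all 8 cells."""
    probs = cell_probability_array(params.as_array(), spec)
    return [
        CellProbability(cell, float(p), float(1.0 - p))
        for cell, p in zip(CELLS, probs)
    ]


def _binom_logpmf(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log pmf with coefficients, safe at p in {0, 1}."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    coef = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(k > 0, k * np.log(p), 0.0)
        term2 = np.where(n - k > 0, (n - k) * np.log1p(-p), 0.0)
    return coef + term1 + term2


def log_likelihood(
    params: QuadParameters | np.ndarray,
    spec: QuadSpecification,
    table: ResponseCountTable,
) -> float:
    """Binomial log-likelihood of a count table under the Quad model.

    Binomial coefficients are included so values are comparable across
    tools.  Returns ``-inf`` exactly when an outcome of probability zero
    has a nonzero count.
    """
    theta = params.as_array() if isinstance(params, QuadParameters) else np.asarray(params)
    p = cell_probability_array(theta, spec)
    nc, ni = table.as_arrays()
    ll = _binom_logpmf(nc, nc + ni, p)
    return float(np.sum(ll))


def simulate_counts(
    params: QuadParameters,
    spec: QuadSpecification,
    trials_per_cell: int | Sequence[int],
    seed: int | np.random.Generator | None = None,
) -> ResponseCountTable:
    """Forward-simulate a count table: n_correct ~ Binomial(n, p_correct)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = np.broadcast_to(np.asarray(trials_per_cell, dtype=int), (8,))
    if np.any(n < 0):
        raise ValueError("trials_per_cell must be nonnegative")
    p = cell_probability_array(params.as_array(), spec)
    ncorrect = rng.binomial(n, p)
    return ResponseCountTable(
        {
            cell: (int(ncorrect[j]), int(n[j] - ncorrect[j]))
            for j, cell in enumerate(CELLS)
        }
    )


def export_equations(spec: QuadSpecification) -> str:
    """Plain-text model equations, one line per cell x outcome.

    Sums of products of parameters, in the spirit of MPT equation files.
    The per-cell guessing symbol is expanded to ``g`` or ``(1 - g)``.
    """
    lines = []
    for cell in CELLS:
        wiring = spec.wiring(cell)
        if wiring.pleasant_correct:
            subst = {"g_cell": "g", "(1 - g_cell)": "(1 - g)"}
        else:  # correct key is the unpleasant-assigned one: g_cell = 1 - g
            subst = {"g_cell": "(1 - g)", "(1 - g_cell)": "g"}
        for outcome in ("correct", "incorrect"):
            products = []
            for path in enumerate_paths(spec, cell):
                if path.outcome != outcome:
                    continue
                expr = str(path)
                expr = expr.replace("(1 - g_cell)", subst["(1 - g_cell)"])
                expr = expr.replace("g_cell", subst["g_cell"])
                products.append(expr)
            lines.append(
                f"{cell[0].value},{cell[1].value},{outcome}: " + " + ".join(products)
            )
    return "\n".join(lines) + "\n"
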