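"""Self-contained synthetic datasets with planted structure.

The expression model is log-normal on the log10 working scale: a gene in
panel b under condition c draws ``log10 FPKM ~ Normal(mu_b + delta_{b,c} *
log10(2), sigma)`` — condition effects are specified in log2 units so they
compare directly with the DEG fold-change threshold. Annotations plant a
"Phototransduction" pathway concentrated in one panel and nitrate/nitrite
keyword descriptions in another, with Bernoulli subcellular flags at
panel-specific rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import ExpressionMatrix
from .errors import ParameterError

PHOTO_PATHWAY = "Phototransduction"
PD_DESCRIPTIONS = (
    "nitrate reductase alpha subunit",
    "nitrite reductase (NADH) large subunit",
    "nitrate/nitrite transporter",
)
GENERIC_PATHWAYS = (
    "Ribosome",
    "Oxidative phosphorylation",
    "Two-component system",
    "ABC transporters",
    "Glycolysis / Gluconeogenesis",
)
GENERIC_DESCRIPTIONS = (
    "elongation factor Tu",
    "ATP synthase subunit beta",
    "DNA-directed RNA polymerase",
    "chaperone protein DnaK",
    "hypothetical protein",
)

LOG10_2 = np.log10(2.0)


def _default_effects() -> np.ndarray:
    # rows: panels; columns: conditions (dark, blue, yellow) in log2 units
    return np.array(
        [
            [0.0, 3.0, 0.0],
            [0.0, 0.0, 3.0],
            [0.0, -3.0, 3.0],
        ]
    )


@dataclass
class FixtureSpec:
    """Parameters of the planted dataset."""

    n_genes: int = 600
    n_panels: int = 3
    conditions: dict[str, int] = field(
        default_factory=lambda: {"dark": 3, "blue": 3, "yellow": 3}
    )
    base_log10: tuple[float, ...] = (1.0, 1.5, 2.0)
    effects_log2: np.ndarray = field(default_factory=_default_effects)
    noise_sd: float = 0.15
    signal_peptide_rate: tuple[float, ...] = (0.8, 0.1, 0.3)
    transmembrane_rate: tuple[float, ...] = (0.1, 0.7, 0.3)
    photo_panel: int = 0
    photo_n_genes: int = 30
    photo_concentration: float = 0.9
    pd_panel: int = 1
    pd_n_genes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        self.effects_log2 = np.asarray(self.effects_log2, dtype=float)
        if self.n_panels < 1 or self.n_genes < 10 * self.n_panels:
            raise ParameterError("need >= 10 genes per panel")
        if self.effects_log2.shape != (self.n_panels, len(self.conditions)):
            raise ParameterError(
                "effects_log2 must be (n_panels, n_conditions), got "
                f"{self.effects_log2.shape}"
            )
        if not np.isfinite(self.effects_log2).all():
            raise ParameterError("effect sizes must be finite")
        for rates in (self.signal_peptide_rate, self.transmembrane_rate):
            if len(rates) != self.n_panels or any(not 0 <= r <= 1 for r in rates):
                raise ParameterError("flag rates must be per-panel values in [0,1]")

    @property
    def condition_names(self) -> list[str]:
        return list(self.conditions)

    def sample_ids(self) -> list[str]:
        return [
            f"{cond}_{rep + 1}"
            for cond, n in self.conditions.items()
            for rep in range(n)
        ]

    def design(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_ids()}

    def panel_sizes(self) -> list[int]:
        base = self.n_genes // self.n_panels
        sizes = [base] * self.n_panels
        sizes[-1] += self.n_genes - base * self.n_panels
        return sizes


def generate_expression(spec: FixtureSpec) -> tuple[ExpressionMatrix, pd.Series]:
    """Planted-block expression matrix plus ground-truth panel labels."""
    rng = np.random.default_rng(spec.seed)
    sizes = spec.panel_sizes()
    labels = np.repeat(np.arange(spec.n_panels), sizes)
    gene_ids = [f"gene_{i:05d}" for i in range(spec.n_genes)]

    cols = []
    for ci, (cond, nrep) in enumerate(spec.conditions.items()):
        mu = np.array(
            [spec.base_log10[b] + spec.effects_log2[b, ci] * LOG10_2 for b in labels]
        )
        for _ in range(nrep):
            cols.append(10.0 ** rng.normal(mu, spec.noise_sd))
    data = pd.DataFrame(
        np.column_stack(cols), index=gene_ids, columns=spec.sample_ids()
    )
    expr = ExpressionMatrix(data, spec.design())
    truth = pd.Series(labels + 1, index=gene_ids, name="panel")
    return expr, truth


def generate_annotations(spec: FixtureSpec, truth: pd.Series) -> pd.DataFrame:
    """Annotations aligned to the fixture's ground-truth panels.

    The planted photo pathway places ``photo_concentration`` of its genes in
    ``photo_panel``; PD keyword descriptions go to genes of ``pd_panel``.
    Subcellular flags are Bernoulli at panel-specific rates (seeded
    independently of the expression noise).
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = list(truth.index)
    labels = truth.to_numpy() - 1

    signal = np.zeros(len(genes), dtype=bool)
    trans = np.zeros(len(genes), dtype=bool)
    for b in range(spec.n_panels):
        mask = labels == b
        signal[mask] = rng.random(mask.sum()) < spec.signal_peptide_rate[b]
        trans[mask] = rng.random(mask.sum()) < spec.transmembrane_rate[b]

    pathways: list[list[str]] = [
        [GENERIC_PATHWAYS[i % len(GENERIC_PATHWAYS)]] for i in range(len(genes))
    ]
    descriptions = [
        GENERIC_DESCRIPTIONS[i % len(GENERIC_DESCRIPTIONS)] for i in range(len(genes))
    ]

    photo_in = np.flatnonzero(labels == spec.photo_panel)
    photo_out = np.flatnonzero(labels != spec.photo_panel)
    n_in = min(int(round(spec.photo_n_genes * spec.photo_concentration)), len(photo_in))
    n_out = min(spec.photo_n_genes - n_in, len(photo_out))
    chosen = np.concatenate(
        [
            rng.choice(photo_in, size=n_in, replace=False),
            rng.choice(photo_out, size=n_out, replace=False),
        ]
    )
    for idx in chosen:
        pathways[idx] = pathways[idx] + [PHOTO_PATHWAY]

    pd_candidates = np.flatnonzero(labels == spec.pd_panel)
    n_pd = min(spec.pd_n_genes, len(pd_candidates))
    for j, idx in enumerate(rng.choice(pd_candidates, size=n_pd, replace=False)):
        descriptions[idx] = PD_DESCRIPTIONS[j % len(PD_DESCRIPTIONS)]

    return pd.DataFrame(
        {
            "signal_peptide": signal,
            "transmembrane": trans,
            "pathway": [";".join(p) for p in pathways],
            "pathways": pathways,
            "description": descriptions,
        },
        index=pd.Index(genes, name="gene_id"),
    )


def generate_dataset(spec: FixtureSpec):
    """Convenience: (expression, annotations, ground-truth labels)."""
    expr, truth = generate_expression(spec)
    annot = generate_annotations(spec, truth)
    return expr, annot, truth


def generate_graph_toy(
    n_nodes: int, geometry: str = "blocks", seed: int = 0
) -> np.ndarray:
    """Deterministic layouts with analytically enumerable edge sets.

    - ``line``: collinear points with gaps 1, 10, 100, ...
    - ``hexagon``: n_nodes must be 6; unit-circumradius regular hexagon.
    - ``blocks``: two tight standard-normal/10 blobs separated by 100 in x.
    """
    if n_nodes < 2:
        raise ParameterError("need at least 2 nodes")
    if geometry == "line":
        xs = np.concatenate([[0.0], np.cumsum(10.0 ** np.arange(n_nodes - 1))])
        return np.column_stack([xs, np.zeros(n_nodes)])
    if geometry == "hexagon":
        if n_nodes != 6:
            raise ParameterError("hexagon geometry requires exactly 6 nodes")
        angles = np.arange(6) * np.pi / 3.0
        return np.column_stack([np.cos(angles), np.sin(angles)])
    if geometry == "blocks":
        rng = np.random.default_rng(seed)
        half = n_nodes // 2
        a = rng.normal(0.0, 0.1, size=(half, 2))
        b = rng.normal(0.0, 0.1, size=(n_nodes - half, 2)) + np.array([100.0, 0.0])
        return np.vstack([a, b])
    raise ParameterError(f"unknown geometry {geometry!r}")
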