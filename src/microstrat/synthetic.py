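"""Synthetic cohort generator with known ground truth.

Emulates a two-time-point prospective child cohort: ~70 subjects sampled
twice, a small number of latent community "steady states" with distinct
genus-level composition and a biodiversity gradient, latent dietary groups
expressed through a 50-item food-frequency questionnaire, and clinical
metadata whose inflammatory markers track the community diversity gradient.

All generators are pure functions of ``(config, seed)``: the same
:class:`SyntheticConfig` always yields byte-identical outputs.  Counts are
Dirichlet-multinomial (overdispersed relative to a plain multinomial, as in
real 16S data); library sizes are lognormal around ``reads_per_sample``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from skbio import TreeNode

from .associations import FfqTable
from .community import OtuTable

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "default_food_reference",
    "generate_tree",
    "generate_otu_table",
    "generate_ffq",
    "generate_metadata",
    "generate_cohort",
]

# inflammatory / clinical markers: name -> (baseline, scale)
MARKERS = {
    "CRP": (0.8, 0.6),              # mg/L
    "IL6": (1.6, 0.5),              # pg/mL
    "IL8": (6.0, 1.5),              # pg/mL
    "IL15": (2.2, 0.5),             # pg/mL
    "TNFa": (5.5, 1.0),             # pg/mL
    "IP10": (120.0, 25.0),          # pg/mL
    "triglycerides": (65.0, 12.0),  # mg/dL
    "diastolic_bp": (62.0, 4.0),    # mmHg
    "glucose": (86.0, 3.0),         # mg/dL
}


def default_food_reference() -> pd.DataFrame:
    """Packaged 50-item food table: group, health value and per-serving
    macronutrients.  Values are a plausible composite of European child-diet
    food lists; all overridable through :class:`SyntheticConfig`."""
    with resources.files("microstrat.data").joinpath("food_reference.csv").open() as fh:
        return pd.read_csv(fh, index_col="food")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    ``state_diversity_gradient`` gives one Dirichlet concentration per latent
    state, ordered so that larger values produce more even genus profiles and
    therefore higher expected Shannon diversity.  ``inflammation_effect`` is
    the slope of each standardized marker against the latent (low-diversity)
    community gradient score.
    """

    n_subjects: int = 70
    n_timepoints: int = 2
    n_otus: int = 200
    n_genera: int = 40
    n_states: int = 4
    n_diet_groups: int = 5
    reads_per_sample: int = 5000
    state_diversity_gradient: tuple = (0.3, 1.0, 3.0, 10.0)
    inflammation_effect: float = 1.0
    marker_noise_sd: float = 1.0
    within_subject_stability: float = 0.75
    sample_concentration: float = 50.0   # Dirichlet-multinomial overdispersion
    library_size_cv: float = 0.395       # lognormal spread of library sizes
    diet_confusion: np.ndarray | None = None   # states x diet groups, row-stochastic
    diet_template_spread: float = 3.0    # strength of the healthy<->unhealthy gradient
    ffq_noise_shape: float = 25.0        # gamma shape; larger = less noisy diets
    food_reference: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.n_diet_groups < 2:
            raise ValueError("n_diet_groups must be >= 2")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        grad = np.asarray(self.state_diversity_gradient, dtype=float)
        if grad.size != self.n_states or (grad <= 0).any():
            raise ValueError(
                "state_diversity_gradient needs exactly n_states strictly positive entries"
            )

    def resolved_confusion(self) -> np.ndarray:
        """State -> diet-group assignment probabilities (row-stochastic)."""
        if self.diet_confusion is not None:
            M = np.asarray(self.diet_confusion, dtype=float)
            if M.shape != (self.n_states, self.n_diet_groups):
                raise ValueError("diet_confusion must be n_states x n_diet_groups")
            if (M < 0).any() or not np.allclose(M.sum(axis=1), 1.0):
                raise ValueError("diet_confusion rows must be non-negative and sum to 1")
            return M
        M = np.full((self.n_states, self.n_diet_groups), 0.45 / (self.n_diet_groups - 1))
        for s in range(self.n_states):
            M[s, s % self.n_diet_groups] = 0.55
        return M


@dataclass
class SyntheticCohort:
    otu_table: OtuTable
    tree: TreeNode
    ffq: FfqTable
    metadata: pd.DataFrame          # indexed by sample id
    truth: pd.DataFrame             # sample -> subject, timepoint, state, diet_group
    genus_cags: pd.Series           # ground-truth genus block labels
    config: SyntheticConfig


def generate_tree(n_otus: int, seed: int) -> TreeNode:
    """Random rooted binary tree over ``n_otus`` uniquely named tips.

    Built by coalescent-style random pairwise joins with exponential branch
    lengths; every branch length is strictly positive.
    """
    if n_otus < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"OTU{i + 1:05d}") for i in range(n_otus)]
    for node in nodes:
        node.length = float(rng.exponential(0.5) + 1e-3)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        parent.length = float(rng.exponential(0.5) + 1e-3)
        nodes.append(parent)
    root = TreeNode(children=nodes)
    root.length = None
    return root


def _taxonomy(n_otus: int, n_genera: int, rng: np.random.Generator):
    """OTU -> genus assignment and Greengenes-style lineage strings."""
    phyla = ["Bacteroidetes", "Firmicutes", "Proteobacteria", "Actinobacteria"]
    genus_names = [f"Genus{g + 1:03d}" for g in range(n_genera)]
    genus_phylum = [phyla[g % len(phyla)] for g in range(n_genera)]
    # every genus gets at least one OTU; remainder assigned at random
    assign = np.concatenate([
        np.arange(n_genera),
        rng.integers(0, n_genera, size=n_otus - n_genera),
    ]) if n_otus >= n_genera else rng.integers(0, n_genera, size=n_otus)
    rng.shuffle(assign)
    lineages = []
    for g in assign:
        lineages.append(
            f"k__Bacteria;p__{genus_phylum[g]};c__Class{g % 7 + 1};"
            f"o__Order{g % 11 + 1};f__Family{g % 13 + 1:02d};g__{genus_names[g]}"
        )
    return assign, lineages, genus_names


def _assign_states(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Subject/timepoint layout with latent state labels.

    The first time point draws the state uniformly; later time points keep
    the subject's previous state with probability ``within_subject_stability``
    and otherwise resample uniformly from the remaining states.
    """
    rows = []
    for s in range(cfg.n_subjects):
        subject = f"S{s + 1:03d}"
        prev = None
        for t in range(cfg.n_timepoints):
            if prev is None or rng.random() < cfg.within_subject_stability:
                state = prev if prev is not None else int(rng.integers(cfg.n_states))
            else:
                others = [x for x in range(cfg.n_states) if x != prev]
                state = int(others[rng.integers(len(others))])
            prev = state
            tp = f"T{2 * t + 1}"  # T1, T3: two surveys four years apart
            rows.append({"sample": f"{subject}.{tp}", "subject": subject,
                         "timepoint": tp, "state": state})
    return pd.DataFrame(rows).set_index("sample")


def generate_otu_table(config: SyntheticConfig):
    """Dirichlet-multinomial OTU counts around state-specific profiles.

    Returns ``(OtuTable, truth, genus_assignment)`` where `truth` holds the
    per-sample subject, time point and latent state, and `genus_assignment`
    maps each genus to its ground-truth co-abundance block (= the state whose
    profile gives it the highest share).
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    assign, lineages, genus_names = _taxonomy(cfg.n_otus, cfg.n_genera, rng)
    grad = np.asarray(cfg.state_diversity_gradient, dtype=float)
    # state genus profiles: higher concentration -> more even -> more diverse
    genus_profiles = np.vstack([
        rng.dirichlet(np.full(cfg.n_genera, grad[s])) for s in range(cfg.n_states)
    ])
    # within-genus OTU split shared across states
    split = np.zeros(cfg.n_otus)
    for g in range(cfg.n_genera):
        idx = np.flatnonzero(assign == g)
        w = rng.dirichlet(np.ones(idx.size))
        split[idx] = w
    otu_profiles = np.vstack([
        genus_profiles[s][assign] * split for s in range(cfg.n_states)
    ])
    otu_profiles /= otu_profiles.sum(axis=1, keepdims=True)

    truth = _assign_states(cfg, rng)
    sigma = np.sqrt(np.log1p(cfg.library_size_cv ** 2))
    counts = np.zeros((len(truth), cfg.n_otus), dtype=int)
    for i, state in enumerate(truth["state"].to_numpy()):
        alpha = np.maximum(cfg.sample_concentration * otu_profiles[state], 1e-3)
        p = rng.dirichlet(alpha)
        depth = max(10, int(round(cfg.reads_per_sample * np.exp(rng.normal(-sigma ** 2 / 2, sigma)))))
        counts[i] = rng.multinomial(depth, p)
    otu_ids = [f"OTU{i + 1:05d}" for i in range(cfg.n_otus)]
    table = OtuTable(
        counts=pd.DataFrame(counts, index=truth.index, columns=otu_ids),
        taxonomy=pd.Series(lineages, index=otu_ids),
    )
    genus_block = pd.Series(
        [int(np.argmax(genus_profiles[:, g])) for g in range(cfg.n_genera)],
        index=genus_names, name="cag_truth",
    )
    return table, truth, genus_block


def generate_ffq(config: SyntheticConfig, truth_states: pd.Series):
    """Food-frequency table conditioned on the latent community states.

    Each diet group has a consumption template ``base * exp(g_d * spread *
    (hv - mean hv))`` along a healthy <-> unhealthy gradient; samples draw
    gamma-noised consumptions around their group's template.  The diet label
    is drawn from the state via the configured confusion matrix.  Returns
    ``(FfqTable, diet_labels)``.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    ref = cfg.food_reference if cfg.food_reference is not None else default_food_reference()
    hv = ref["health_value"].to_numpy()
    base = ref["base_daily"].to_numpy()
    loading = hv - hv.mean()
    gradient = np.linspace(-1.0, 1.0, cfg.n_diet_groups)
    templates = np.vstack([
        base * np.exp(g * cfg.diet_template_spread * loading) for g in gradient
    ])
    M = cfg.resolved_confusion()
    states = pd.Series(truth_states)
    diets = np.array([
        rng.choice(cfg.n_diet_groups, p=M[s]) for s in states.to_numpy()
    ])
    shape = cfg.ffq_noise_shape
    cons = np.vstack([
        rng.gamma(shape, templates[d] / shape) for d in diets
    ])
    ffq = FfqTable(
        consumption=pd.DataFrame(cons, index=states.index, columns=ref.index),
        annotations=ref,
    )
    return ffq, pd.Series(diets, index=states.index, name="diet_group")


def _state_gradient_scores(cfg: SyntheticConfig) -> np.ndarray:
    """Standardized per-state score increasing towards LOW diversity, so a
    positive ``inflammation_effect`` raises markers in low-diversity states."""
    grad = np.asarray(cfg.state_diversity_gradient, dtype=float)
    raw = -np.log(grad)
    return (raw - raw.mean()) / (raw.std() if raw.std() > 0 else 1.0)


def generate_metadata(
    config: SyntheticConfig,
    otu_table: OtuTable,
    truth: pd.DataFrame,
):
    """Ages, gender, activity/education scores, weight status and markers.

    Every marker is ``baseline + scale * (effect * z_state + noise)`` with
    ``z_state`` the standardized low-diversity gradient score of the sample's
    latent state.  The follow-up obesity label is enriched in low-diversity
    states through a logistic model on the subject's mean gradient score.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    z = _state_gradient_scores(cfg)
    rows = []
    subjects = truth["subject"].unique()
    base_age = {s: float(np.round(rng.uniform(6.0, 10.0), 1)) for s in subjects}
    gender = {s: ("F" if rng.random() < 0.5 else "M") for s in subjects}
    zbar = truth.assign(z=[z[s] for s in truth["state"]]).groupby("subject")["z"].mean()
    p_obese = 1.0 / (1.0 + np.exp(-0.8 * zbar))
    obese_subject = {s: bool(rng.random() < p_obese[s]) for s in subjects}
    for sample, row in truth.iterrows():
        t_index = int(row["timepoint"][1:])  # T1 -> 1, T3 -> 3
        age = base_age[row["subject"]] + (0.0 if t_index == 1 else 4.0)
        zs = z[row["state"]]
        rec = {
            "sample": sample,
            "subject": row["subject"],
            "timepoint": row["timepoint"],
            "age": age,
            "gender": gender[row["subject"]],
            "develops_obesity": obese_subject[row["subject"]],
            "weight_status": (
                "obese" if (t_index == 3 and obese_subject[row["subject"]]) else "normal"
            ),
            "mvpa_score": float(np.round(max(5.0, rng.normal(60.0, 20.0)), 1)),
            "education_score": int(np.clip(np.round(rng.normal(4.0, 1.5)), 1, 8)),
        }
        for marker, (baseline, scale) in MARKERS.items():
            val = baseline + scale * (
                cfg.inflammation_effect * zs + rng.normal(0.0, cfg.marker_noise_sd)
            )
            rec[marker] = float(np.round(max(val, 0.01), 4))
        rows.append(rec)
    return pd.DataFrame(rows).set_index("sample")


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate the complete synthetic cohort (table, tree, FFQ, metadata)."""
    cfg = config
    table, truth, genus_block = generate_otu_table(cfg)
    tree = generate_tree(cfg.n_otus, seed=cfg.seed + 10_000)
    ffq, diet = generate_ffq(cfg, truth["state"])
    metadata = generate_metadata(cfg, table, truth)
    truth = truth.copy()
    truth["diet_group"] = diet
    return SyntheticCohort(
        otu_table=table, tree=tree, ffq=ffq, metadata=metadata,
        truth=truth, genus_cags=genus_block, config=cfg,
    )
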