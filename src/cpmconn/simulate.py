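"""Synthetic multi-site connectome datasets with planted ground truth.

The generator emulates the structure of a multisite autism severity study:
a model sample (~150 patients), an independent validation sample (~170
patients), and a small healthy-control sample (~36 subjects), each with
160-node Fisher-z connectomes, behavioural severity scores (a total score
and three subscores), confounded covariates (age, sex, head motion), and
additive + multiplicative per-site (scanner) effects on every edge.

A sparse set of "planted" edges is linearly coupled to the standardized
behavioural score (negatively, by default), so that every downstream stage
— harmonization, edge selection, cross-validated prediction, external
validation, specificity, network anatomy — can be tested by recovery of a
known ground truth. Control subjects receive low scores and *no* edge
coupling, making specificity tests expected-null by construction.

Randomness is driven by one integer seed through a documented hierarchy of
``numpy.random.SeedSequence`` substreams (truth, baseline, per-sample
draws, time series), so identical specs and seeds give bit-identical
datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    Atlas,
    ConnectivityMatrix,
    TimeSeriesMatrix,
    devectorize,
    EdgeVector,
    edge_index,
    n_edges,
)

logger = logging.getLogger("cpmconn")

#: Canonical six-network parcellation names.
SIX_NETWORKS = ["default", "fronto-parietal", "cingulo-opercular",
                "sensorimotor", "occipital", "cerebellum"]

#: Substream order under the master seed; indexes into SeedSequence.spawn.
_STREAMS = {"truth": 0, "baseline": 1, "model": 2, "validation": 3,
            "control": 4, "timeseries": 5}


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic study.

    Defaults are frozen study conditions: sample sizes mirror the target
    design (150 model / 170 validation / 36 control), the behavioural score
    is ADOS-total-like (mean ~11.9, SD ~4 in patients; ~1.3 in controls),
    covariate distributions follow typical multisite phenotype tables
    (age ~ U(7, 40) years; heavily male samples; mFD lognormal with mean
    ~0.08-0.10 mm), and 40 planted negative edges couple to the score with
    ``beta`` = 1.5 Fisher-z units per behaviour SD against unit edge noise.
    """

    n_model: int = 150
    n_validation: int = 170
    n_control: int = 36
    n_nodes: int = 160
    n_networks: int = 6
    #: planted (i, j, sign) with 0-based i < j; None -> sample n_true_edges
    true_edge_set: list | None = None
    n_true_edges: int = 40
    true_edge_sign: int = -1
    beta: float = 1.5
    noise_sd: float = 1.0
    #: slopes of behaviour on (centred) covariates, ADOS units per unit
    covariate_effects: dict = field(default_factory=lambda: {
        "age": 0.05, "sex": -1.0, "mfd": 8.0})
    score_mean: float = 11.9
    score_sd: float = 3.9          # residual SD on top of covariate effects
    control_score_mean: float = 1.33
    control_score_sd: float = 1.66
    p_male: float = 0.94
    mfd_log_sd: float = 0.4
    mfd_mean: float = 0.09         # mm, lognormal mean
    edge_mu_mean: float = 0.25     # population mean edge weight (Fisher z)
    edge_mu_sd: float = 0.20
    n_sites: dict = field(default_factory=lambda: {
        "model": 4, "validation": 2, "control": 1})
    site_gamma_mean_sd: float = 0.10   # spread of per-site overall offsets
    site_gamma_sd: float = 0.20        # per-edge additive spread within site
    site_delta_log_sd: float = 0.15    # per-edge multiplicative (log) spread
    subtype_probs: dict = field(default_factory=lambda: {
        "CA": 0.73, "AS": 0.20, "PDD-NOS": 0.07})
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.site_delta_log_sd < 0:
            raise ValueError("site scale spread must be >= 0")
        if self.true_edge_set is not None:
            E_pairs = set()
            for (i, j, s) in self.true_edge_set:
                if not (0 <= i < j < self.n_nodes):
                    raise ValueError(
                        f"true edge ({i},{j}) outside upper triangle of "
                        f"{self.n_nodes}-node matrix")
                if s not in (-1, 1):
                    raise ValueError("true edge sign must be -1 or +1")
                E_pairs.add((i, j))
            if len(E_pairs) != len(self.true_edge_set):
                raise ValueError("duplicate true edges")


@dataclass
class SyntheticDataset:
    """One generated study: edges, phenotypes, and the realized truth.

    ``pheno`` carries a ``sample`` column ({model, validation, control});
    ``edges`` rows align with ``pheno`` rows and hold the canonical
    upper-triangle edge vector of each subject's connectome.
    """

    edges: np.ndarray
    pheno: pd.DataFrame
    n_nodes: int
    truth: dict

    def sample(self, name: str) -> tuple[np.ndarray, pd.DataFrame]:
        """(edges, phenotype) restricted to one sample, row-aligned."""
        m = (self.pheno["sample"] == name).to_numpy()
        if not m.any():
            raise KeyError(f"no such sample: {name}")
        return self.edges[m], self.pheno.loc[m].reset_index(drop=True)

    def connectomes(self, name: str | None = None) -> list[ConnectivityMatrix]:
        """Rebuild full symmetric connectomes (optionally for one sample)."""
        if name is None:
            edges, pheno = self.edges, self.pheno
        else:
            edges, pheno = self.sample(name)
        return [
            devectorize(EdgeVector(subject_id=sid, values=row,
                                   n_nodes=self.n_nodes))
            for sid, row in zip(pheno["subject_id"], edges)
        ]

    @property
    def true_mask_vector(self) -> np.ndarray:
        """Length-E signed vector of planted edges (canonical edge order)."""
        iu, ju = edge_index(self.n_nodes)
        key = {(i, j): s for i, j, s in self.truth["true_edges"]}
        return np.array([key.get((i, j), 0) for i, j in zip(iu, ju)], dtype=int)


def make_atlas(n_nodes: int, n_networks: int = 6) -> Atlas:
    """Synthetic atlas: nodes assigned to networks in contiguous blocks.

    Network names reuse the canonical six resting-state names (cycled if
    ``n_networks`` > 6); coordinates are a deterministic 3-D lattice.
    """
    names = [SIX_NETWORKS[k % len(SIX_NETWORKS)] if k < 6 else f"net{k + 1}"
             for k in range(n_networks)]
    net = [names[min(k * n_networks // n_nodes, n_networks - 1)]
           for k in range(n_nodes)]
    g = int(np.ceil(n_nodes ** (1 / 3)))
    idx = np.arange(n_nodes)
    t = pd.DataFrame({
        "node_id": idx + 1,
        "label": [f"node{k + 1:03d}" for k in idx],
        "network": net,
        "x": (idx % g) * 10.0 - 45.0,
        "y": ((idx // g) % g) * 10.0 - 45.0,
        "z": (idx // (g * g)) * 10.0 - 20.0,
    })
    return Atlas(table=t)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _spawn(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(children[k])
            for name, k in _STREAMS.items()}


def _true_edges(spec: GeneratorSpec, rng) -> list[tuple[int, int, int]]:
    if spec.true_edge_set is not None:
        return [tuple(e) for e in spec.true_edge_set]
    E = n_edges(spec.n_nodes)
    pick = rng.choice(E, size=spec.n_true_edges, replace=False)
    iu, ju = edge_index(spec.n_nodes)
    return [(int(iu[k]), int(ju[k]), spec.true_edge_sign) for k in sorted(pick)]


def _site_sizes(n: int, k: int) -> list[int]:
    """Deterministic, mildly unbalanced split of n subjects over k sites.

    Imbalance is kept gentle enough that the default 150-subject model
    sample leaves every site with >= 20 subjects (sites below that are
    excluded by the study's filtering rule, and the generator emulates the
    post-exclusion site structure).
    """
    w = np.array([1.3 ** (k - 1 - i) for i in range(k)])
    sizes = np.floor(n * w / w.sum()).astype(int)
    sizes[0] += n - sizes.sum()
    return sizes.tolist()


def _sample_pheno(spec: GeneratorSpec, name: str, n: int, rng) -> pd.DataFrame:
    age = rng.uniform(7, 40, n)
    sex = np.where(rng.random(n) < spec.p_male, "M", "F")
    mfd_mu = np.log(spec.mfd_mean) - 0.5 * spec.mfd_log_sd ** 2
    mfd = np.exp(rng.normal(mfd_mu, spec.mfd_log_sd, n))
    is_control = name == "control"
    if is_control:
        subtype = np.array(["HC"] * n)
    else:
        labels = list(spec.subtype_probs)
        probs = np.array([spec.subtype_probs[s] for s in labels], dtype=float)
        subtype = rng.choice(labels, size=n, p=probs / probs.sum())
    sizes = _site_sizes(n, spec.n_sites[name])
    site = np.repeat([f"{name.upper()[:3]}_{i + 1}" for i in range(len(sizes))],
                     sizes)
    return pd.DataFrame({
        "subject_id": [f"{name[:3]}{i + 1:04d}" for i in range(n)],
        "sample": name,
        "group": "control" if is_control else "patient",
        "subtype": subtype,
        "site": site,
        "age": age,
        "sex": sex,
        "mfd": mfd,
        "fiq": rng.normal(105, 12, n),
        "handedness": "right",
        "n_timepoints": rng.integers(120, 300, n),
        "max_motion_mm": np.abs(rng.normal(0.5, 0.3, n)),
        "max_motion_deg": np.abs(rng.normal(0.5, 0.3, n)),
    })


def _behaviour(spec: GeneratorSpec, pheno: pd.DataFrame, rng) -> pd.DataFrame:
    """Scores = baseline + covariate effects + noise (patients); low-mean
    uncoupled scores for controls. Returns pheno with score columns added,
    plus the latent standardized severity used for edge coupling."""
    n = len(pheno)
    if (pheno["group"] == "control").all():
        total = np.clip(rng.normal(spec.control_score_mean,
                                   spec.control_score_sd, n), 0, None)
        latent = np.zeros(n)  # no edge coupling for controls
    else:
        cov_term = np.zeros(n)
        for cov, slope in spec.covariate_effects.items():
            v = pheno[cov]
            v = (v == "M").astype(float) if v.dtype == object else v.astype(float)
            cov_term += slope * (v - v.mean())
        total = spec.score_mean + cov_term + rng.normal(0, spec.score_sd, n)
        total = np.clip(total, 0, None)
        latent = (total - total.mean()) / total.std()
    p = pheno.copy()
    p["score_total"] = total
    b = latent if latent.std() > 0 else np.zeros(n)
    p["score_social"] = np.clip(8.1 + 2.4 * b + rng.normal(0, 1.5, n), 0, None)
    p["score_communication"] = np.clip(3.9 + 1.3 * b + rng.normal(0, 0.9, n),
                                       0, None)
    p["score_rrb"] = np.clip(2.1 + 0.8 * b + rng.normal(0, 1.5, n), 0, None)
    if (pheno["group"] == "control").all():
        for c in ("score_social", "score_communication", "score_rrb"):
            p[c] = np.clip(rng.normal(0.6, 1.0, n), 0, None)
    p["_latent"] = latent
    return p


def _sample_edges(spec: GeneratorSpec, pheno: pd.DataFrame, mu: np.ndarray,
                  sign_vec: np.ndarray, coupled: bool, rng) -> tuple[np.ndarray, dict]:
    """Edge matrix for one sample: mu + coupling + site effects + noise."""
    n, E = len(pheno), len(mu)
    latent = pheno["_latent"].to_numpy()
    sites = list(dict.fromkeys(pheno["site"]))
    gamma = {}
    delta = {}
    for s in sites:
        g0 = rng.normal(0, spec.site_gamma_mean_sd)
        gamma[s] = rng.normal(g0, spec.site_gamma_sd, E)
        delta[s] = np.exp(rng.normal(0, spec.site_delta_log_sd, E))
    noise = rng.normal(0, spec.noise_sd, (n, E))
    z = np.tile(mu, (n, 1))
    if coupled:
        z += spec.beta * np.outer(latent, sign_vec)
    for s in sites:
        rows = (pheno["site"] == s).to_numpy()
        z[rows] += gamma[s][None, :]
        noise[rows] *= delta[s][None, :]
    z += noise
    return z, {"gamma": gamma, "delta": delta}


def generate(spec: GeneratorSpec) -> SyntheticDataset:
    """Generate the full synthetic study (model + validation + control).

    Reproducible: the same spec (including its ``seed``) gives bit-identical
    output. See the module docstring for the generative model.
    """
    rngs = _spawn(spec.seed)
    true_edges = _true_edges(spec, rngs["truth"])
    E = n_edges(spec.n_nodes)
    mu = rngs["baseline"].normal(spec.edge_mu_mean, spec.edge_mu_sd, E)

    iu, ju = edge_index(spec.n_nodes)
    pos = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))}
    sign_vec = np.zeros(E)
    for (i, j, s) in true_edges:
        sign_vec[pos[(i, j)]] = s

    frames, blocks, site_params = [], [], {}
    for name, n in (("model", spec.n_model), ("validation", spec.n_validation),
                    ("control", spec.n_control)):
        if n == 0:
            continue
        rng = rngs[name]
        pheno = _sample_pheno(spec, name, n, rng)
        pheno = _behaviour(spec, pheno, rng)
        coupled = name != "control"
        z, sp = _sample_edges(spec, pheno, mu, sign_vec, coupled, rng)
        frames.append(pheno)
        blocks.append(z)
        site_params[name] = sp

    pheno = pd.concat(frames, ignore_index=True)
    latent = pheno.pop("_latent").to_numpy()
    return SyntheticDataset(
        edges=np.vstack(blocks),
        pheno=pheno,
        n_nodes=spec.n_nodes,
        truth={
            "spec": spec,
            "true_edges": true_edges,
            "latent_behaviour": latent,
            "mu": mu,
            "site_params": site_params,
        },
    )


# ---------------------------------------------------------------------------
# Time-series emission
# ---------------------------------------------------------------------------

def _nearest_pd_correlation(R: np.ndarray, eps: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Clip eigenvalues at eps and renormalize to unit diagonal."""
    w, V = np.linalg.eigh((R + R.T) / 2)
    repaired = bool(w.min() < eps)
    if repaired:
        w = np.clip(w, eps, None)
        R = (V * w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        R = (R + R.T) / 2
    np.fill_diagonal(R, 1.0)
    return R, repaired


def timeseries_for_connectome(cm: ConnectivityMatrix, T: int,
                              rng: np.random.Generator) -> TimeSeriesMatrix:
    """Gaussian node series whose population correlation is ``tanh(z)``.

    The target correlation matrix is repaired to the nearest
    positive-definite correlation matrix (eigenvalue clipping at 1e-6,
    logged) before sampling, so ``compute_connectome`` on the output
    recovers the (possibly repaired) target within sampling error.
    """
    if T < 50:
        raise ValueError("need T >= 50 timepoints")
    R = np.tanh(cm.z)
    np.fill_diagonal(R, 1.0)
    R, repaired = _nearest_pd_correlation(R)
    if repaired:
        logger.info("timeseries %s: target correlation repaired to PD",
                    cm.subject_id)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as e:  # pragma: no cover - guarded by repair
        raise ValueError(f"target correlation for {cm.subject_id} is not "
                         f"repairable to positive definite") from e
    g = rng.standard_normal((T, cm.n_nodes))
    return TimeSeriesMatrix(subject_id=cm.subject_id, values=g @ L.T)


def generate_timeseries(spec: GeneratorSpec, T: int,
                        sample: str = "model") -> list[TimeSeriesMatrix]:
    """Generate a sample's subjects as node time series (see module doc)."""
    ds = generate(spec)
    rng = _spawn(spec.seed)["timeseries"]
    return [timeseries_for_connectome(cm, T, rng)
            for cm in ds.connectomes(sample)]
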