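"""Empirical-Bayes site harmonization."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from cpmconn import combat_fit_transform
from cpmconn.harmonize import covariate_matrix


def _two_site_data(rng, n=60, G=40, offset=2.0, slope=0.5, noise=0.3):
    site = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    b = rng.normal(size=n)
    Y = rng.normal(0, noise, (n, G)) + slope * b[:, None]
    Y[site == "B"] += offset
    return Y, site, b


def test_single_site_is_identity(rng):
    Y = rng.normal(size=(20, 15))
    out, model = combat_fit_transform(Y, ["only"] * 20)
    assert np.allclose(out, Y, atol=1e-8)
    assert np.allclose(model.gamma_star, 0)


def test_additive_offset_removed_per_feature(rng):
    # pure +2 shift on every feature of site B, low noise, no covariates
    Y, site, _ = _two_site_data(rng, offset=2.0, slope=0.0, noise=0.1)
    out, _ = combat_fit_transform(Y, site)
    diff = out[site == "B"].mean(axis=0) - out[site == "A"].mean(axis=0)
    assert np.abs(diff).max() <= 0.05


def test_covariate_effect_preserved(rng):
    Y, site, b = _two_site_data(rng, offset=1.5, slope=0.5, noise=0.3)
    out, _ = combat_fit_transform(Y, site, b[:, None])
    design = np.column_stack([np.ones(len(b)), b])
    slopes = np.linalg.lstsq(design, out, rcond=None)[0][1]
    assert np.abs(slopes.mean() - 0.5) < 0.05
    assert np.all(np.abs(slopes - 0.5) < 0.5 * 0.1 + 3 * 0.3 / np.sqrt(len(b)))


def test_subject_order_invariance(rng):
    Y, site, b = _two_site_data(rng)
    out, _ = combat_fit_transform(Y, site, b[:, None])
    perm = rng.permutation(len(site))
    out_p, _ = combat_fit_transform(Y[perm], site[perm], b[perm, None])
    assert np.allclose(out_p, out[perm], atol=1e-8)


def test_approximate_idempotence(rng):
    Y, site, b = _two_site_data(rng)
    once, _ = combat_fit_transform(Y, site, b[:, None])
    twice, _ = combat_fit_transform(once, site, b[:, None])
    scale = np.abs(once - once.mean(axis=0)).mean()
    assert np.abs(twice - once).mean() < 0.05 * scale


def test_parametric_and_nonparametric_agree_under_gaussian_effects(rng):
    Y, site, b = _two_site_data(rng, n=80, G=200)
    par, _ = combat_fit_transform(Y, site, b[:, None], mode="parametric")
    non, _ = combat_fit_transform(Y, site, b[:, None], mode="nonparametric")
    assert np.abs(par - non).mean() < 0.05 * Y.std()


def test_site_anova_collapses_after_harmonization():
    """Generated site effects inflate a one-way site ANOVA across edges;
    harmonization removes them (median F drops below the null median)."""
    from scipy.stats import f_oneway
    from cpmconn import GeneratorSpec, generate
    from cpmconn.pipeline import usable_covariates

    ds = generate(GeneratorSpec(n_model=100, n_validation=0, n_control=0,
                                n_nodes=30, n_true_edges=10, seed=0))
    em, pm = ds.sample("model")
    site = pm["site"].to_numpy()
    covs = usable_covariates(pm, ["age", "sex", "fiq", "mfd"])
    out, _ = combat_fit_transform(em, site, covariate_matrix(pm, covs),
                                  covariate_names=covs)
    idx = np.random.default_rng(9).choice(em.shape[1], 100, replace=False)

    def median_f(X):
        groups = [X[site == s] for s in sorted(set(site))]
        return np.median([f_oneway(*[g[:, e] for g in groups]).statistic
                          for e in idx])

    assert median_f(em) > 1.2     # site effects visible before
    assert median_f(out) < 0.8    # at or below the null median after


def test_singleton_site_errors_unless_allowed(rng):
    Y = rng.normal(size=(11, 5))
    site = ["A"] * 10 + ["B"]
    with pytest.raises(ValueError, match="single subject"):
        combat_fit_transform(Y, site)
    out, model = combat_fit_transform(Y, site, allow_singleton_sites=True)
    assert np.all(np.isfinite(out))
    assert np.allclose(model.delta_star[1], 1.0)


def test_collinear_covariates_named(rng):
    Y = rng.normal(size=(20, 5))
    site = ["A"] * 10 + ["B"] * 10
    c = rng.normal(size=20)
    C = np.column_stack([c, 2 * c])
    with pytest.raises(ValueError, match="cov1"):
        combat_fit_transform(Y, site, C, covariate_names=["cov0", "cov1"])


def test_covariate_matrix_encodings():
    pheno = pd.DataFrame({"subject_id": ["a", "b"], "sex": ["M", "F"],
                          "group": ["patient", "control"], "age": [10, 20.0]})
    C = covariate_matrix(pheno, ["sex", "group", "age"])
    assert np.array_equal(C, [[1, 1, 10], [0, 0, 20]])


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_matches_reference_combat_implementation(tmp_path, rng):
    """Independent oracle: Bioconductor sva::ComBat on the same data."""
    n, G = 30, 20
    site = np.array(["A"] * 16 + ["B"] * 14)
    C = rng.normal(size=(n, 2))
    Y = rng.normal(size=(n, G)) + C @ rng.normal(size=(2, G)) * 0.5
    Y[site == "B"] += rng.normal(0.8, 0.3, G)[None, :]
    np.savetxt(tmp_path / "Y.csv", Y, delimiter=",")
    np.savetxt(tmp_path / "C.csv", C, delimiter=",")
    (tmp_path / "site.txt").write_text("\n".join(site) + "\n")
    script = f"""
    suppressMessages(library(sva))
    Y <- as.matrix(read.csv("{tmp_path}/Y.csv", header=FALSE))
    C <- as.matrix(read.csv("{tmp_path}/C.csv", header=FALSE))
    site <- readLines("{tmp_path}/site.txt")
    par <- ComBat(dat=t(Y), batch=site, mod=cbind(1, C), par.prior=TRUE)
    non <- ComBat(dat=t(Y), batch=site, mod=cbind(1, C), par.prior=FALSE)
    write.table(t(par), "{tmp_path}/r_par.csv", sep=",", row.names=FALSE, col.names=FALSE)
    write.table(t(non), "{tmp_path}/r_non.csv", sep=",", row.names=FALSE, col.names=FALSE)
    """
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    r_par = np.loadtxt(tmp_path / "r_par.csv", delimiter=",")
    r_non = np.loadtxt(tmp_path / "r_non.csv", delimiter=",")
    py_par, _ = combat_fit_transform(Y, site, C, mode="parametric")
    py_non, _ = combat_fit_transform(Y, site, C, mode="nonparametric")
    assert np.abs(py_par - r_par).max() < 1e-4   # fixed-point tolerance
    assert np.abs(py_non - r_non).max() < 1e-10
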