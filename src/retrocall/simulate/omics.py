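"""Synthetic count / gene / methylation tables with planted effects.

Generative models (all seeded):

* TE counts — negative binomial per TE and sample; a chosen subset of TEs
  carries a mean fold change between the two groups.
* Gene table — TSS positions uniform on a genome; a subset of genes lies
  near planted TE features; upregulation is Bernoulli with logistic
  log-odds ``b0 + b1 * near`` (``b1 = 0`` is the null).
* Methylation — per-dyad methylation drawn beta-binomial: level ~
  Beta(mu, rho), methylated ~ Binomial(coverage, level); the KO group of
  target dyads has its mean shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class OmicsSpec:
    """Distributions and effect sizes for the omics-table generator."""

    # TE counts
    n_te: int = 200
    n_de: int = 10
    nb_mean: float = 100.0
    de_fold: float = 8.0
    nb_dispersion: float = 0.1  # Var = mu + dispersion * mu^2
    n_replicates: int = 3
    # genes / TSS proximity
    n_genes: int = 1000
    genome_len: int = 100_000_000
    n_features: int = 60
    feature_len: int = 5000
    proximity_window: int = 100_000
    base_up_logit: float = -3.0  # ~5% upregulated baseline
    proximity_effect: float = 0.0  # added log-odds of upregulation when near
    # methylation
    n_dyads: int = 1000
    meth_mean_wt: float = 0.8
    meth_shift_ko: float = 0.0  # added to target-group mean in KO
    meth_precision: float = 30.0  # beta precision (a + b)
    meth_coverage: float = 20.0  # Poisson mean, floored at 1
    frac_target_dyads: float = 0.5

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.meth_precision <= 0:
            raise ValueError("precision must be > 0")


def _nb_draw(rng, mean, dispersion, size):
    # NB parameterized by mean and dispersion alpha: Var = mu + alpha mu^2
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_te_counts(spec: OmicsSpec, seed: int = 0):
    """TE count table (rows te_0000.., columns wt_*/ko_*) plus truth
    labels (boolean Series: planted differential TEs, upregulated in KO)."""
    rng = np.random.default_rng(seed)
    n, k = spec.n_te, spec.n_replicates
    de = np.zeros(n, dtype=bool)
    de[: spec.n_de] = True
    wt = _nb_draw(rng, spec.nb_mean, spec.nb_dispersion, size=(n, k))
    ko_mean = np.where(de, spec.nb_mean * spec.de_fold, spec.nb_mean)
    ko = np.column_stack(
        [_nb_draw(rng, ko_mean, spec.nb_dispersion, size=n) for _ in range(k)]
    )
    index = pd.Index([f"te_{i:04d}" for i in range(n)], name="insertion_id")
    cols = [f"wt_{j+1}" for j in range(k)] + [f"ko_{j+1}" for j in range(k)]
    table = pd.DataFrame(np.column_stack([wt, ko]), index=index, columns=cols)
    truth = pd.Series(de, index=index, name="is_de")
    return table, truth


def simulate_gene_tss_table(spec: OmicsSpec, seed: int = 0):
    """Gene table (gene_id, chrom, tss, strand, status) plus TE feature
    intervals and per-gene truth (near flag, P(up) used)."""
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    starts = rng.integers(0, spec.genome_len - spec.feature_len, size=spec.n_features)
    features = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.sort(starts),
            "end": np.sort(starts) + spec.feature_len,
        }
    )
    tss = rng.integers(0, spec.genome_len, size=spec.n_genes)
    fs, fe = features["start"].to_numpy(), features["end"].to_numpy()
    near = np.array(
        [
            bool(
                np.any(
                    np.where(
                        (fs <= t) & (t < fe),
                        0,
                        np.minimum(np.abs(fs - t), np.abs(t - (fe - 1))),
                    )
                    <= spec.proximity_window
                )
            )
            for t in tss
        ]
    )
    logit = spec.base_up_logit + spec.proximity_effect * near
    p_up = 1.0 / (1.0 + np.exp(-logit))
    up = rng.random(spec.n_genes) < p_up
    status = np.where(up, "up", "ns")
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene_{i:05d}" for i in range(spec.n_genes)],
            "chrom": chrom,
            "tss": tss,
            "strand": np.where(rng.random(spec.n_genes) < 0.5, "+", "-"),
            "status": status,
        }
    )
    truth = pd.DataFrame({"gene_id": genes["gene_id"], "near": near, "p_up": p_up})
    return genes, features, truth


def simulate_methylation(spec: OmicsSpec, seed: int = 0):
    """Per-cytosine call tables for WT and KO (chrom, pos, strand,
    coverage, methylated) plus per-dyad truth (group, mean used).

    Dyads are split into a ``target`` group (mean shifted by
    ``meth_shift_ko`` in KO) and a ``background`` group. Both strands of
    each dyad are emitted as separate cytosine calls.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_dyads
    positions = np.sort(rng.choice(np.arange(1000, 10_000_000, 2), size=n, replace=False))
    target = np.zeros(n, dtype=bool)
    target[: int(spec.frac_target_dyads * n)] = True

    def draw_calls(mean_by_dyad):
        rho = spec.meth_precision
        a = np.clip(mean_by_dyad * rho, 1e-6, None)
        b = np.clip((1 - mean_by_dyad) * rho, 1e-6, None)
        level = rng.beta(a, b)
        rows = []
        for strand_offset, strand in ((0, "+"), (1, "-")):
            cov = np.maximum(rng.poisson(spec.meth_coverage / 2, size=n), 1)
            meth = rng.binomial(cov, level)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": "chr1",
                        "pos": positions + strand_offset,
                        "strand": strand,
                        "coverage": cov,
                        "methylated": meth,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True).sort_values(["pos", "strand"]).reset_index(drop=True)

    mean_wt = np.full(n, spec.meth_mean_wt)
    mean_ko = np.where(
        target,
        np.clip(spec.meth_mean_wt + spec.meth_shift_ko, 0.001, 0.999),
        spec.meth_mean_wt,
    )
    wt_calls = draw_calls(mean_wt)
    ko_calls = draw_calls(mean_ko)
    truth = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": positions,
            "group": np.where(target, "target", "background"),
            "mean_wt": mean_wt,
            "mean_ko": mean_ko,
        }
    )
    return wt_calls, ko_calls, truth


def simulate_omics_tables(spec: OmicsSpec | None = None, seed: int = 0):
    """All three omics fixtures from one spec and seed.

    Returns a dict: ``te_counts`` (table, truth), ``genes`` (genes,
    features, truth), ``methylation`` (wt_calls, ko_calls, truth).
    """
    spec = spec or OmicsSpec()
    return {
        "te_counts": simulate_te_counts(spec, seed=seed),
        "genes": simulate_gene_tss_table(spec, seed=seed + 1),
        "methylation": simulate_methylation(spec, seed=seed + 2),
    }
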