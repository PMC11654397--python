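# rarcat

Robustness Assessment of Regressions using Cluster Analysis Typologies.

A common design in state sequence analysis (and far beyond it) first
clusters trajectories into a typology and then regresses cluster membership
on covariates.  Both steps are estimated from one sample, yet the sampling
uncertainty of the *typology itself* is usually ignored — a new sample can
yield different clusters, different memberships, and therefore different
regression conclusions.  `rarcat` quantifies that risk: it replicates the
whole pipeline on bootstrap resamples, collects the regression effects at
the individual level (side-stepping the impossibility of mapping clusters
across bootstraps), and pools them with a meta-analytic mixed model into a
robust effect estimate, a prediction interval for the effect in a new
sample, and trajectory-level diagnostics.  It is written for
epidemiologists and quantitative social scientists who use sequence
typologies in association studies.

## The procedure

Given M categorical state sequences, a covariate table and an original
typology (Optimal Matching distances with transition-rate substitution
costs, indel = half the maximum cost, maximal cost for the missing state;
deterministic PAM; K chosen by ASW/CHI):

1. Draw a bootstrap sample of size M with replacement.
2. Re-cluster it with the identical procedure (same distance matrix, same
   algorithm, K fixed or re-estimated by maximising CHI).
3. Fit one logistic regression per bootstrap cluster ("this cluster vs.
   any other", identical covariates) and compute the average marginal
   effect (AME) of the covariate of interest with its SE.
4. Assign each cluster's AME to every distinct individual in it.
5. Repeat N times (default 1000), giving an M×N effect matrix `Y` with an
   entry only where the individual was drawn and its cluster's fit
   succeeded.
6. For the individuals of a reference cluster in the *original* typology,
   pool the entries with a cross-classified weighted mixed model

       Y_ij = a00 + u_i + v_j + e_ij,
       u_i ~ N(0, σ_u²), v_j ~ N(0, σ_v²), e_ij ~ N(0, σ_e²·SE_ij²),

   fitted by REML with inverse-variance weights.  `a00` is the pooled AME;
   σ_v captures between-bootstrap (i.e. between-typology) variation and
   yields the 95% prediction interval
   `a00 ∓ t_{N−2} · sqrt(s_v² + SE(a00)²)`; the BLUPs `u_i` separate
   central from outlier trajectories within the cluster.

Cluster-wise bootstrap Jaccard stability (Hennig) is reported alongside,
and two alternative pooling specifications (individual fixed effects;
inverse-hyperbolic-tangent transform) serve as sensitivity checks.  See
`docs/methods.md` for the full model account.

## Worked example

Everything below is reproducible with the built-in generator, which
emulates a 5-year healthcare-utilisation cohort (states: no utilisation /
emergency / hospitalisation / both / dead / missing; a binary exposure and
a comorbidity confounder shifting latent type membership):

```python
import numpy as np
from rarcat import (CovariateTerm, RarcatConfig, SimulationConfig,
                    classify_trajectories, clusterwise_jaccard,
                    fit_crossed_reml, pam, pairwise_matrix, pooling_input,
                    prediction_interval, run_rarcat, simulate_dataset,
                    trate_costs, transition_rates)

cfg = SimulationConfig(n=348, seed=1)          # true exposure AME ~ 0.22
seqs, types, mixture = simulate_dataset(cfg)
costs = trate_costs(transition_rates(seqs), cfg.missing_code)
dist = pairwise_matrix(seqs, costs)
typology = pam(dist, k=3, compute_indices=True)
stab = clusterwise_jaccard(typology, dist, n_boot=100, seed=1)
config = RarcatConfig(
    covariates=[CovariateTerm("exposure", "binary"),
                CovariateTerm("comorbidities", "numeric")],
    covariate_of_interest="exposure", n_boot=500, seed=1,
    k_mode="fixed", k=3)
result = run_rarcat(seqs, dist, typology, config)
fit = fit_crossed_reml(pooling_input(result, typology, cluster=1))
pi = prediction_interval(fit, n_boot=config.n_boot)

print(f"typology: K=3, sizes={np.bincount(typology.labels)[1:].tolist()}, "
      f"ASW={typology.asw:.2f}, CHI={typology.chi:.0f}")
print("cluster-wise Jaccard:", [round(v, 2) for v in stab.mean_jaccard])
print(f"pooled AME={fit.a00:.3f} (SE {fit.se_a00:.3f}), "
      f"s_u={fit.s_u:.3f}, s_v={fit.s_v:.3f}")
print(f"95% PI [{pi.lower:.3f}, {pi.upper:.3f}]")
cats = classify_trajectories(fit)["category"].value_counts().to_dict()
print("trajectories:", cats)
```

Printed output:

```
typology: K=3, sizes=[207, 91, 50], ASW=0.71, CHI=798
cluster-wise Jaccard: [1.0, 1.0, 1.0]
pooled AME=0.226 (SE 0.003), s_u=0.011, s_v=0.054
95% PI [0.119, 0.333]
trajectories: {'central': 205, 'outlier': 2}
```

Reading it: the three-cluster typology is highly stable (Jaccard 1.0 —
every cluster is recovered in essentially every bootstrap).  The pooled
exposure effect on membership in cluster 1 (the no-utilisation type) is
0.226 — a 22.6-percentage-point higher membership probability for exposed
individuals — close to the generator's true effect of ≈ 0.225.  The small
SE (0.003) says 500 replicates are plenty; s_v = 0.054 says a re-estimated
typology on a new sample would move the effect by about ±0.05, giving the
95% prediction interval [0.119, 0.333], which excludes zero: this
association survives the robustness assessment.  Two trajectories have
BLUPs more than one s_u from the cluster mean and are flagged as outliers —
candidates for borderline, in-between sequences.

The same pipeline is available from the shell:

```bash
rarcat simulate --n 348 --seed 1 --out-prefix syn
rarcat typology  --states syn_states.csv --covariates syn_covariates.csv \
                 --alphabet none,emergency,hospital,both,dead,missing --k 3
rarcat run  --states syn_states.csv --covariates syn_covariates.csv \
            --alphabet none,emergency,hospital,both,dead,missing --k 3 \
            --n-boot 500 --seed 1 \
            --covariate-terms exposure:binary,comorbidities:numeric \
            --covariate-of-interest exposure --out-prefix rc
rarcat pool --ame-long rc_long.csv --partition rc_partition.csv \
            --cluster 1 --n-boot 500
```

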