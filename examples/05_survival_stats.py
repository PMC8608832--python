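"""Tour of the survival evaluation stack on one simulated dataset.

Concordance with a bootstrap CI, Cox and Fine-Gray fits, Kaplan-Meier
with log-rank, continuous NRI, incidence rates, and the two-proportion
sample-size design.
"""

import numpy as np

import cinerisk.stats as ss

rng = np.random.default_rng(0)
n = 300
score = rng.normal(size=n)  # risk score with a true log-hazard slope of 0.8
t_event = rng.exponential(1 / (0.08 * np.exp(0.8 * score)))
t_death = rng.exponential(1 / 0.04, size=n)  # independent competing death
time = np.minimum(np.minimum(t_event, t_death), 10.0)
code = np.where(time == t_event, 1, np.where(time == t_death, 2, 0))
event = (code == 1).astype(int)

c, npairs = ss.concordance_index(score, time, event)
est, lo, hi = ss.bootstrap_ci(
    lambda idx: ss.concordance_index(score[idx], time[idx], event[idx])[0],
    n, n_resamples=100, seed=1,
)
print(f"C-index {c:.3f} over {npairs} comparable pairs (bootstrap 95% CI {lo:.3f}-{hi:.3f})")

cox = ss.fit_cox(score[:, None], time, event, names=["score"])
print(f"Cox HR per unit score: {cox.hazard_ratios['score']:.2f} "
      f"(95% CI {cox.ci_95['score'][0]:.2f}-{cox.ci_95['score'][1]:.2f}, p={cox.p_values['score']:.2g})")

fg = ss.fine_gray(score[:, None], time, code, names=["score"])
print(f"Fine-Gray subdistribution HR (death competing): {fg.hazard_ratios['score']:.2f}")

groups = ss.dichotomize_at_quantile(score, 0.5)
low, high = groups == "low", groups == "high"
km_low = ss.kaplan_meier(time[low], event[low])
chi2, p = ss.log_rank_test([(time[low], event[low]), (time[high], event[high])])
print(f"10-year survival, low-score group: {km_low.survival_at(10.0):.2f}; "
      f"log-rank chi2={chi2:.1f}, p={p:.2g}")

noisy = score + rng.normal(0, 1.5, n)  # a weaker comparator marker
print(f"continuous NRI of score over the noisy comparator: "
      f"{ss.nri_continuous(noisy, score, event):+.3f}")

rate, (rlo, rhi) = ss.incidence_rate(int(event.sum()), float(time.sum()))
print(f"incidence {rate:.2f} per 100 person-years (95% CI {rlo:.2f}-{rhi:.2f})")

npg, ntot = ss.sample_size_two_proportions(0.877, 0.740, alpha=0.05, power=0.90)
print(f"two-group design for survival fractions 0.877 vs 0.740 at 90% power: "
      f"{npg}/group, {ntot} total")
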