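"""Independent direct-simulation oracle for rejection rate / power.

Re-implements the calibration-geometry generative model and the median
permutation test definition in plain numpy, without importing tamscan.
Geometry: 1 chromosome x 1 Mb, 100 windows of 10 kb, no mask, 100
mutations, zero_fraction 0.3, lognormal(0, 1.5) rates, profile noise
lognormal(0, 0.3), read_depth 2, tie rule greater_or_equal, alpha 0.05.
"""
import numpy as np
import sys

N_WIN = 100
WLEN = 10_000
ZERO_FRAC = 0.30
LOG_MU, LOG_SIGMA = 0.0, 1.5
PROFILE_SIGMA = 0.30
READ_DEPTH = 2.0
N_MUT = 100
N_PERM = 10_000
ALPHA = 0.05


def one_pvalue(rng, beta):
    lam = np.where(rng.random(N_WIN) < ZERO_FRAC, 0.0,
                   rng.lognormal(LOG_MU, LOG_SIGMA, N_WIN))
    lam_prof = lam * rng.lognormal(0.0, PROFILE_SIGMA, N_WIN)
    cov_sum = rng.poisson(lam_prof * READ_DEPTH * WLEN)
    rate = cov_sum / WLEN
    tpm = 1e6 * rate / rate.sum() if rate.sum() > 0 else np.zeros(N_WIN)
    z = np.log1p(lam)
    sd = z.std()
    z = (z - z.mean()) / sd if sd > 0 else np.zeros(N_WIN)
    w = np.exp(beta * z - (beta * z).max())
    hit = rng.choice(N_WIN, size=N_MUT, p=w / w.sum())
    flagged = np.unique(hit)
    k = flagged.size
    obs = np.median(tpm[flagged])
    null = np.empty(N_PERM)
    for i in range(N_PERM):
        null[i] = np.median(tpm[rng.choice(N_WIN, size=k, replace=False)])
    return np.mean(null >= obs)


def power(beta, reps, seed0):
    rej = 0
    for r in range(reps):
        rng = np.random.default_rng(seed0 + r)
        rej += one_pvalue(rng, beta) < ALPHA
    return rej / reps


if __name__ == "__main__":
    reps = int(sys.argv[1]) if len(sys.argv) > 1 else 400
    for beta in (0.0, 0.5, 1.0, 1.5, 2.0):
        p = power(beta, reps, seed0=10_000 + int(beta * 1000))
        se = (p * (1 - p) / reps) ** 0.5
        print(f"beta={beta:.1f} power={p:.4f} se={se:.4f}")
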