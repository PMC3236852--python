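# Methods

## Model

A Boolean network G(V, F) on n genes is a list of predictor sets and truth
tables; all genes update synchronously, so the deterministic dynamics are a
map f on {0,1}^n. States are indexed by the decimal value of (x_1 … x_n)
with x_1 the most significant bit; gene indices are 0-based in memory and
1-based in JSON files. A BNp adds an i.i.d. per-gene flip probability
p ∈ (0,1): at each step the network follows f with probability (1−p)^n,
otherwise a uniformly random non-empty gene subset flips. The chain's TPM
decomposes as P = (1−p)^n Q + H with H[x,y] = p^h(x,y) (1−p)^(n−h(x,y)) off
the diagonal and 0 on it; each H row sums to 1 − (1−p)^n. Perturbation
makes the chain irreducible and aperiodic, so the SSD exists, is unique and
strictly positive.

Stuck-at mutations only touch Q. The transformation matrix T_{i,k}
(T[s, force(s,i,k)] = 1) is idempotent; Q T_{i,k} equals Q rebuilt from the
truth-table-mutated network, so mutation application commutes and a path is
a *set* of mutations. The TPM change of one mutation decomposes into at
most 2^(n−1) rank-one terms, one per moved column s → s′ of Q:
a = (1−p)^n Q[:,s], b = e_{s′} − e_s (terms with empty columns omitted).

## Stationary-distribution computation

The reference path is a direct linear solve of π(P − I) = 0 with the
normalisation row Σπ = 1, validated by the residual ‖πP − π‖∞ < 1e−8 and
falling back to the leading left eigenvector when the bordered system is
singular. The analytical path applies the rank-one terms sequentially
through the fundamental matrix Z = [I − P + eπ^T]^(−1):

    π̃ = π + (π·a)/(1 − bZa) · bZ,

recomputing Z after each term (the intermediate matrices remain valid
ergodic TPMs because each term only moves deterministic mass between two
columns while H stays intact). The exact algebraic arrangement of this
update was adopted from Markov-chain perturbation theory and is *gated by
equivalence tests* against the direct solve rather than trusted: the suite
checks agreement to 1e−9 over 200 random (network, mutation) instances at
n = 3…6 and order-invariance of path application to 1e−10. A denominator
within 1e−12 of zero triggers a direct-solve fallback. The detection
algorithm itself uses the direct solve (at n ≤ 8 one 2^n×2^n solve is
sub-millisecond); the rank-one path is exposed as the analytical machinery.

## Distance and residual

Networks are compared via their SSDs with ρ = KL divergence (natural log).
Because a distance between two networks must be symmetric, the default
combination is the Jeffreys-type average d = [ρ(π1,π2) + ρ(π2,π1)]/2;
`sum` and `max` variants are available and differ only by a global scale /
ordering, which shifts all thresholds consistently. Probabilities are
floored at 1e−300 before the log purely to guard hand-built fixtures; BNp
SSDs are strictly positive. The residual of candidate N at perturbation p
is d(SSD(N_p), SSD_cancer).

## Threshold calibration (distance CDFs)

F_D^(m,p) — the CDF of the distance between a random BNp and its m-mutation
copy — is estimated from ensembles of random networks with exactly k
predictors per gene and Bernoulli(p_b) truth tables, mutations drawn
uniformly over distinct genes and stuck-at values. The default ensemble
size is 4000 networks (a fast mode of a few hundred is used in unit tests).
Samples are smoothed with a Gaussian-kernel CDF, Silverman bandwidth
0.9·min(sd, IQR/1.34)·N^(−1/5), reflected at zero so no mass lies below
d = 0; a degenerate sample falls back to the empirical step CDF. Quantiles
are found by bisection (smallest d with F(d) ≥ q). Fitted CDFs can be
cached on disk keyed by the full parameter tuple. The estimator is checked
against the empirical CDF (sup-distance ≤ 0.05 at 4000 samples) and for
quantile stability under ensemble doubling (< 5% of the median-distance
scale; the 0.1 quantile sits near zero, so a relative criterion there would
measure noise, not drift).

## Detection algorithm

Step j of M expands every surviving (origin network, path) pair by all
2(n − j + 1) admissible single mutations, computes each proposal's
residual, and keeps those with residual ≤ β_j (inclusive, so β = 0 retains
exact matches). β_j for j < M is the p_j-quantile of F_D^(M−j, p) — the
candidate still differs from the cancerous chain by M−j mutations — giving
β_1 ≥ … ≥ β_{M−1} when the CDFs come from one ensemble family; β_M
defaults to 0.1, far above the true pair's zero residual. Pairs reaching
the same (origin, unordered path) are merged at the end of each step;
iteration order (origin, gene, value) is fixed, so results are
bit-reproducible. Every proposal counts one residual computation, matching
the closed-form count Σ_j |ℱ_{j−1}|·2(n−j+1); duplicate altered chains
within a step reuse the cached residual without changing the count. An
empty survivor set ends the run with the failing step recorded.

## Performance metrics

P_miss is modelled by assuming that at step j each of the M−j+1
single-mutation extensions of the true path survives independently with
probability p_j, and that the final step is certain (zero residual under
β_M = 0.1): P_miss = 1 − Π_{j=1}^{M−1}[1 − (1−p_j)^(M−j+1)], reducing to
(1−p_1)^2 at M = 2. The form is validated two ways: against the eight
tabulated reference values (two-decimal agreement) and against a Monte
Carlo simulation of the survival process written as an independent oracle.
P_c(ε) is the probability that no surviving origin network lies within ε
SSD-distance of the true normal network; ε defaults to {0.05, 0.1}
(configurable — the reference values for ε are not fixed by the problem).

The experiment driver plants a canalizing normal network (random canalizing
input/value/output per gene, remaining entries Bernoulli(p_b)) inside a
family of Bernoulli(p_b) networks on the same wiring, mutates it along a
uniform random M-path, computes the cancerous SSD at p_cancer, derives
thresholds from CDFs built at the algorithm's p (p ≠ p_cancer gives model
mismatch studies), and aggregates both metrics with binomial standard
errors. Default study conditions follow the synthetic experiments: n = 6,
k = 2, p_b = 0.3, p_cancer = 0.001, M = 2 (and n = 8, M = 3 variants via
configuration). Replicate counts default to 100 families of 20 networks —
a deliberate scaled-down design that preserves the experiment's structure
while keeping a full run to minutes on one CPU; the closed-form P_miss is
independent of family size.

## Case-study harness and fixture

`run_case_study` enumerates the full uncertainty class from a don't-care
map (per-gene columns over all 2^n states with entries 0/1/X; enumeration
guard u_X ≤ 20), plants a mutation path on a designated consistent normal
network, and reports per-p the final number of networks, (network, path)
pairs, distinct paths and a success flag (exact planted pair among the
survivors). The shipped 4-gene fixture is a *synthetic* DNA-damage-response
module in the style of the ATM–p53–Wip1–Mdm2 circuit with 12 undetermined
entries (family size 4096); it reproduces the structure, not the published
truth tables, of pathway-derived maps.

## What the synthetic generators do and do not show

The random-network ensembles emulate the structural statistics
(connectivity, bias, canalizing normal networks) of the reference study's
synthetic families; they do not emulate real expression data — no
measurement noise on the SSD, no unknown M, no deviation from the BNp
update model. Passing tests therefore demonstrate correctness of the
machinery and fidelity of the algorithm's statistical behaviour under the
model, not performance on tissue data. Known limitations: dense 2^n×2^n
matrices cap practical n near 12; the number of mutations M must be given;
thresholds inherit the Monte Carlo error of the CDF ensembles; and when
M/n is large, mutated networks collapse onto similar SSDs and the
uncertainty class cannot be reduced much — the regulatory signal itself is
destroyed, not the algorithm's bookkeeping.
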