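# Methods

## The models

All five families describe the irreversible accumulation of binary
events: a genotype is the subset of events present in one individual,
events are gained one at a time, and a gained event is never lost.
Under these assumptions a model induces a process on the genotype
lattice, starting at the wild type (WT, the empty set).

**Restriction-DAG families (OT, CBN, OncoBN, H-ESBCN).** A DAG over the
events plus an implicit virtual root states which events must precede
which. A node's *relation* says how multiple parents combine before the
child may be gained: AND (all parents present), OR (at least one), XOR
(exactly one). OT is the tree-restricted case (≤1 parent, relation
always Single); CBN allows AND only; OncoBN allows AND or OR but one
relation type per model (conjunctive vs disjunctive form); H-ESBCN
allows all three. The virtual root never appears in genotypes or data.

**Timed vs untimed.** CBN and H-ESBCN attach an exponential rate
`λ_e > 0` to each node: the waiting time to gain a satisfiable event is
exponential and events compete. OT and OncoBN are untimed: each node
carries the conditional probability in (0,1) that the event is present
*by observation time* given its dependency is met, and the genotype
distribution is the Bayesian-network product over nodes (a genotype
violating a restriction has probability 0). This makes OT a special
case of conjunctive OncoBN and the two share one code path.

**MHN.** No DAG; an n×n real matrix θ specifies the process completely.
The rate of gaining event *e* from genotype *g* is
`exp(θ_ee) · Π_{i∈g} exp(θ_ei)`: a baseline hazard modulated by
pairwise multiplicative effects, promoting (θ>0) or inhibiting (θ<0).
Every rate is strictly positive, so all 2^n genotypes are reachable and
the only absorbing state is the full genotype.

## Observation distribution

Cross-sectional sampling is modelled as censoring the CTMC at an
independent time `T ~ Exponential(s)`, default `s = 1`. Only the ratio
of event rates to the sampling rate is identifiable, so `s` fixes the
time unit; scaling all rates and `s` by the same constant leaves the
distribution unchanged (tested). With `R(g)` the total exit rate of `g`
the probability of ever visiting `g` before T obeys

    ρ(WT) = 1,   ρ(h) = Σ_{g→h} ρ(g) · Q[g,h] / (s + R(g)),

and the observed mass of `g` is `ρ(g) · s / (s + R(g))`. Because adding
an event strictly increases the genotype's bit pattern, the canonical
state order (by event count, then numeric value) is topological and one
forward pass suffices; the same fact makes `sI − Q` triangular, which
the test suite exploits to cross-check the pass against an independent
linear solve, and the Gillespie simulator provides a third,
sampling-based route. The jump chain (`P[g,h] = Q[g,h]/R(g)`) excludes
the observation event; absorbing rows are left all-zero rather than
identity so path enumeration terminates cleanly.

## Paths

An evolutionary path is a WT-to-absorbing sequence of single gains. For
timed families its probability is the product of jump-chain steps — the
probability of that event order conditional on full progression,
observation excluded — so path probabilities always sum to 1. Untimed
models define no dynamics; as a stated convention the step probability
of event `e` at `g` is `param(e)` normalized over the currently
satisfiable absent events. Under XOR the constraint binds at the moment
the child is gained: a second XOR parent may be gained afterwards, so
accessibility is path-dependent and the breadth-first closure (not a
static per-event check) is authoritative. Absorbing genotypes need not
be the full event set (XOR can block a child forever); paths end at any
absorbing state. Enumeration counts paths by dynamic programming first
and refuses (with advice) beyond a configurable cap of 10^6.

## Noise and simulation

Observational (genotyping) error is modelled as independent symmetric
per-cell flips with one probability ε ∈ [0, 0.5] — the simplest model
consistent with a single user-specified error level. Its exact effect
on a distribution is the Hamming-kernel convolution
`P'(h) = Σ_g P(g) ε^d(g,h) (1−ε)^{n−d}`, computed as n per-bit binary
channels (cost n·2^n). ε = 0 is the identity and ε = 0.5 maps any
distribution to uniform. Asymmetric false-positive/negative rates,
per-event rates, missing data, and the "model error" used inside some
original fitting codes are deliberately out of scope; only
observational noise is implemented.

The Gillespie simulator draws `T ~ Exp(s)` per individual and simulates
competing exponential gains until the next gain would pass T. It is
vectorized across individuals over per-state rate tables but remains an
independent code path from the analytic computation, and serves as its
oracle (total-variation < 0.02 at N = 10^5 in the tests). All
randomness flows through `numpy.random.default_rng` with explicit
seeds; identical seeds reproduce byte-identical CSV and JSON outputs.

## Fitting

**OT.** Marginal and pairwise frequencies with a pseudocount of 0.5 in
every 2×2 table cell; edge weight
`w(i→j) = 2·log p_ij − log(p_i + p_j) − log p_i − log p_j`
(relative-occurrence plus association terms, the conventional
oncogenetic-tree weight — isolated in one function since it is a
convention, not a derivation); Edmonds maximum-weight arborescence
rooted at the virtual root (networkx); edge probabilities
`p(child|parent) = p_{c∧p} / p_p`. Columns constant at 0 or 1 carry no
tree signal and are rejected with instructions to remove them.

**MHN.** Exact penalized marginal likelihood on the 2^n lattice:
maximize `Σ_g N_g log p_θ(g) − λ Σ_{i≠j} |θ_ij|`. The smooth part's
gradient is computed analytically by an adjoint pass: one forward
triangular solve for p, one backward solve for the adjoint w, then
`∂L/∂θ_ab = Σ_{g: a∉g, b∈g∪{a}} rate_a(g) · p_g · (w_{g+a} − w_g)`,
at O(n·2^n) per evaluation. Optimization is proximal gradient (ISTA)
with backtracking line search and soft-thresholding of the
off-diagonals, which guarantees the penalized objective is monotone
over accepted iterates (asserted in tests); convergence at relative
objective change < 1e-8 or 500 iterations, with non-convergence flagged
in the diagnostics rather than raised. The diagonal is initialized from
the per-event closed form `θ_ee = log(f_e/(1−f_e))` (exact for n = 1),
off-diagonals at 0. Supported to n = 12 (4096 states).

**CBN rates.** For a fixed DAG, maximum likelihood over log-rates with
L-BFGS-B, sampling rate fixed at 1 for identifiability. Observations
incompatible with the DAG would zero the likelihood; by default the
predicted distribution is convolved with a small flip kernel
(ε = 0.001, exposed as an option; pass 0 for the pure model when the
data are compatible).

Every `FitResult.log_likelihood` is reproducible by re-scoring the data
through the prediction modules (tested to 1e-6). An unpenalized full-θ
MHN is over-parametrized relative to an edgeless CBN, so their *fitted*
diagonals coincide exactly only at n = 1; their *predicted
distributions* coincide at any n when θ is diagonal (both are tested).

CBN structure learning, H-ESBCN and OncoBN fitting, EM over hidden
occurrence times, and model-selection tables are out of scope: H-ESBCN
and OncoBN are simulate/predict-only here.

## Random models

DAGs are generated by drawing a random topological order and adding
edges downward with a given density (OT: each node picks one parent
uniformly among the root and its predecessors, giving a uniform
attachment tree). Default parameter ranges — rates in [0.5, 2],
probabilities in [0.1, 0.9] — were chosen so a typical sample contains
a moderate number of events (neither all-WT nor saturated); they are
configurable and recorded in run manifests. Generated models are
asserted valid and their predicted distributions normalized as a
standing property test.

## Synthetic data and what the tests show

All tests run on synthetic or hand-constructed inputs: closed-form
lattice examples (two independent events; a three-event AND; a
three-event XOR), random models of every family (n ≤ 6), and samples
drawn by the package's own generators. The generator emulates i.i.d.
cross-sectional sampling under the stated model with homogeneous
per-cell genotyping error. Real tumour data violate several of these
idealizations — events can be lost, constraints differ between
patients, noise is asymmetric and structured, and the true model family
is unknown — so passing tests demonstrate correctness of the
computations and internal consistency of the engine, not that any
family describes a given dataset. Problem sizes used by the default
suite and the acceptance script (n ≤ 6 for sweeps, N = 10^4 for fits,
N = 10^5 for simulation checks) were chosen as the smallest at which
the statistical assertions are comfortably stable.

## Numerical choices

* Genotypes are integer bit masks; `n ≤ 12` keeps all dense 2^n
  structures below 4096 states.
* Canonical genotype order (event count, then bit value) everywhere a
  matrix or table is emitted; genotype labels are `"WT"` or event names
  joined by `", "`.
* "Rate is zero" means exactly zero: rates come from parameters, never
  from arithmetic cancellation.
* Distribution normalization is asserted at 1e-9, rate-matrix row sums
  at 1e-12; model JSON round-trips bit-exactly (shortest-repr floats).
* Ties in path ordering are broken lexicographically by the gained
  event sequence, making all outputs deterministic.
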