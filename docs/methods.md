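# Methods

## Scope and model

The package implements an in-silico screening cascade for herbal
compound libraries: oral-absorption gating and CYP-metabolism scoring of
admetSAR-style predictions, diffusion-based target inference on a
substructure–drug–target network, skin-tissue expression filtering,
hypergeometric pathway enrichment, and bipartite compound–target network
construction. Wet-lab stages of the motivating study (cell viability,
melanin content, tyrosinase activity, Western blots) are out of scope
except for the 2^−ΔΔCt quantification arithmetic.

## ADMET scoring

ADMET predictions arrive as *signed probabilities*: the sign is the
predicted class, the magnitude the class probability. The absorption
gate keeps compounds with positive HIA **and** positive Caco-2 calls;
it uses sign only — no probability threshold is applied, because none is
defensible without the underlying classifiers — and magnitudes are
carried for reporting. The metabolism score is

    score = Σ_k result_k · Q_k

over the five major CYP isoforms, with `Q_k` the published overall
predictive accuracy of each isoform's inhibition classifier (defaults
0.8147 / 0.8018 / 0.8551 / 0.8054 / 0.6450 for 1A2 / 2C9 / 2D6 / 2C19 /
3A4; overridable via YAML). The sign convention — inhibitor positive —
is deliberate and load-bearing: the screen *rewards* broad CYP
inhibition, and this convention reproduces the five bundled reference
scores exactly (tolerance 1e-8). The score is bounded by ±Σ Q_k =
±3.9220. Ranking is score-descending with ties broken by compound id
ascending; the reference data contain a genuine tie (two compounds with
identical calls), and no principled ordering exists between them.

## Target inference (SDTNBI)

The inference network is tripartite: substructure keys — drugs —
targets. Known drugs contribute drug→target edges (the DTI set) and
substructure→drug edges (their binary fingerprints). A query compound is
*not* a network node: it injects unit mass through the substructure keys
it shares with the network, which is what makes the method applicable to
new chemical entities. Diffusion is the parameterless degree-normalized
resource-allocation kernel in three hops — equal split over the query's
in-network keys, then over each key's drugs, then over each drug's
targets. The method family admits weighted variants; the published
variants' exact propagation weights are not public, so the base kernel
is the default and `DiffusionParams` exposes per-hop receiving-degree
exponents (normalized within each split, so mass conservation holds for
any exponent; zero recovers the equal split).

Numerical choices:

- **Leak accounting.** Mass reaching a drug with no (remaining) targets
  is reported as `leaked_mass`, never renormalized — renormalization
  would silently inflate the scores of reached targets. The invariant
  `Σ resource + leak = 1` is enforced to 1e-12 and tested against an
  independent path-enumeration oracle on exhaustively enumerated tiny
  networks and random medium ones.
- **Ties** break lexicographically by id everywhere (target ranking,
  compound ranking), making every output deterministic.
- **Degenerate queries** (no in-network substructure) return an empty
  result with leak 1.0 and a warning rather than raising.

Cross-validation holds out DTI edges in k folds (or leave-one-out),
rebuilds the reduced network per fold (degrees recomputed, so no
leakage), re-scores each affected drug through its own fingerprint, and
compares each held-out positive against 10 uniformly sampled non-edges
of the same drug; fold AUC is computed on the pooled scores and all
sampling derives from an explicit seed. An all-tied fold scores 0.5 by
convention.

## Tissue filtering

Expression is ordinal (not_detected < low < medium < high), emulating
antibody-staining export tables. "Expressed" means level ≥ threshold,
default `low` — the least-committal reading of a detection call; the
threshold is an explicit parameter because the boundary between `low`
and `medium` is a judgment call in real atlases. The classifier returns
a strict five-way partition (both / keratinocyte-only / melanocyte-only
/ neither / unmapped) so counts always reconcile with the input.

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k) per gene set (scipy), BH
step-up adjustment across the collection (statsmodels), GMT as the
interchange format. The universe defaults to the union of set members
when not supplied; in pipeline use the DTI network's target set is the
natural universe. DAVID-style modified scores (EASE) are intentionally
not replicated — the plain hypergeometric is exactly testable against
combinatorial summation, which the suite does for every universe size
up to 30.

## Synthetic data

The generators produce every input format with planted ground truth and
emit sidecar truth files so tests never reach into generator internals.
Defaults mirror the motivating study's printed tallies: 48 compounds
split 18/13/11/3/3 across steroids/terpenes/flavonoids/fatty
acids/others, and exactly 37 compounds passing the double absorption
gate (77 %). Every generator is a pure function of `SynthConfig`; same
seed, byte-identical files.

The DTI generator plants the statistical structure the inference method
assumes — substructure sharing predicts target sharing. Twenty of
thirty substructure keys are each associated with one of twenty
targets; a drug carrying a planted key gains the associated target with
probability 0.95, and drugs gain one uniformly random extra target with
probability 0.1 (plus a guarantee of at least one target, so no known
drug is dangling). Carriage rate 0.10 over 100 drugs was chosen so that
each key has ~10 carrier drugs and per-drug profiles stay sparse: denser
carriage flattens drug target-profiles and dilutes the planted signal
below what a "signal-carrying" network should deliver. Query compounds
carry exactly one planted key plus background keys drawn from the
non-planted pool, isolating the pharmacophore whose target the truth
table names.

What the generator does *not* emulate: real chemistry (SMILES are small
valid strings, not natural products), correlated fingerprints, hub
drugs/targets with heavy-tailed degree distributions, and noisy or
biased DTI curation. Passing tests therefore demonstrate that the
machinery recovers signal that is present in the assumed form — not
that real screens of comparable size will reach the same AUC. The
published screen's own tallies that depend on the authors' proprietary
training network, atlas version or enrichment service (102 targets/713
edges, 72/12/5 tissue counts, 36.1 % pathway coverage) are treated as
pipeline contracts, not reproducible numbers.

Gene-set collections place one planted set whose members are sampled
with weight 5 for designated query genes versus 1 otherwise (universe
50, query 15, ten sets of ten by default); expression tables use
per-tissue detection rates (0.8 keratinocyte, 0.7 melanocyte) with
detected levels uniform over low/medium/high.

## Problem sizes

The test suite and the acceptance script run entirely on generated data
at the scale above (≈200-edge networks, 10-fold CV over five seeds,
1,000 diffusion queries, twenty enrichment collections); the full suite
completes in well under a minute on one core. These sizes were chosen as
the smallest at which the planted-signal guarantees are comfortably
stable across seeds.

## Known limitations

- The diffusion kernel is the base case of its method family; published
  weighted variants may rank differently on hub-heavy networks.
- Fingerprints are treated as given; the bundled SMARTS backend is a
  convenience, not a replacement for a curated key dictionary.
- The enrichment universe choice materially affects p-values, and no
  universe is "correct" without knowing the prediction pipeline's reach.
- qPCR fold changes use mean-ΔCt aggregation; efficiency-corrected
  models are out of scope.
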