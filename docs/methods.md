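# Methods

## Model

A biological pathway is abstracted as a directed graph: nodes are
proteins, small molecules and processes; edges point downstream along
signal flow; one node is the designated exit (the measurable output —
PGE2 for the packaged network). Each edge carries a dimensionless
resistance, the edge value EV, equal to 1 in the unperturbed network.

Inhibition is modelled with non-competitive Michaelis–Menten kinetics for
every target (no per-target mechanism switch). The fraction of a target's
activity removed by inhibitors is

    f_a = 1 − 1 / (1 + Σ_i [I_i]/K_i),

which depends only on the summed dose ratio — this "mutually exclusive
inhibitors" form is what makes self-combinations exactly dose-additive
(Loewe-consistent), a property the test suite exploits. One compound may
carry records for several targets (polypharmacology); each target gets
its own f_a from the same concentration.

Every edge leaving an inhibited target is penalised as EV = 10^(2.303·f_a);
all other edges stay at 1. Connectivity is then measured on the weighted
graph:

* NE — sum of reciprocal weighted shortest-path lengths over ordered node
  pairs i ≠ j. The network is directed, so (i, j) and (j, i) count
  separately, and unreachable pairs contribute 0 (the 1/∞ = 0 convention
  of the network-efficiency formalism). This matters: most reverse pairs
  in a signalling pathway are unreachable.
* NF — the same sum restricted to pairs ending at the exit node, which
  up-weights downstream nodes.

Readouts are percent decreases between the all-EV=1 maximum and the
all-EV=200 minimum: NEd, NFd, and their geometric mean NEF — the model's
percent-inhibition predictor. Shortest paths are computed with Dijkstra's
algorithm (all EVs ≥ 1, so non-negative weights); the test suite
cross-checks the engine against a hand-written Floyd–Warshall and, on
tiny graphs, exhaustive simple-path enumeration.

### The two "maximum resistance" constants

The model assumes the most potent inhibitor blocks 99.5 % of its target,
giving a nominal cap of 1/(1 − 0.995) = 200, which is the constant used
for the NE_min/NF_min bounds. The edge-value map, however, literally
evaluates to 10^(2.303·f_a), which reaches 10^2.303 ≈ 200.9 at f_a = 1
(and 195.7 at f_a = 0.995). Both constants are kept where they belong —
Eq.-literal edge values, 200-based bounds — rather than silently
reconciled; the small overshoot can push NEd/NFd marginally past 100 %,
so both are clamped to [0, 100] after the percent formulas (the clamp is
logged at debug level). `EV_BOUND = 200` and `EV_CEIL = 10^2.303` expose
the two constants.

## Units

Binding affinities enter as pKi = −log10(K_I in mol/L), so K_I in μM is
10^(6 − pKi); all doses and EC50s are μM. This convention is fixed
globally and tested (pKi 6 ↔ 1 μM).

## Dose–response curves

A curve is predicted by sweeping a concentration grid through
single-compound scenarios. The default grid has 12 log-spaced points
spanning a 10^4-fold range centred on the half-plateau dose (found by
bisection); monotonicity of the response in dose is a theorem of the
model (raising any EV can only lengthen shortest paths) and is asserted
as a property test.

Curves are fitted with the four-parameter logistic by trust-region
least squares (`scipy.optimize.curve_fit`, tolerances 1e-15, so noiseless
self-generated curves are recovered to ~1e-15 relative). Initialisation:
E_max = max(y), E_min = min(y), EC50 = concentration nearest the
half-maximal response, n = 1. Default bounds E_min ∈ [−20, 20] and
E_max ∈ [80, 120] reflect percent-inhibition data plateauing near 100 %;
when the observed plateau is below 80 % the E_max band is widened to
[0.75·max(y), 1.5·max(y)], because a compound touching few network
targets saturates well short of full inhibition and must not be forced
onto a 100 %-plateau sigmoid. Degenerate inputs (fewer than 5 points, a
flat curve) raise a `FitError` rather than returning garbage.

The EC50 agreement statistic regresses experimental EC50s on predicted
ones by ordinary least squares. For n = 5 compounds the ordinary R² and
its small-sample adjusted form differ visibly (0.945 vs 0.927); both are
computed and the adjusted form is the headline value. OLS R² equals the
squared Pearson correlation, so the statistic is invariant under swapping
which list is the regressor — asserted as a test.

## Combinations

Two-drug scenarios share targets through the summed dose ratio and
penalise exclusive targets independently; the resulting NEF over a dose
grid is the dose–response surface. Chou's combination index at a dose
pair (D_a, D_b) uses the jointly attained effect x and the single-drug
doses (D_x) producing x alone. The (D_x) values are obtained by bisecting
the model's own monotone NEF curve (relative dose tolerance 1e-6) rather
than the fitted Hill curve, so no fit error propagates into CI; zero
doses drop their term, and a single non-zero dose yields CI = 1
identically (the definition degenerates to D/(D_x) with D = (D_x)).

Isoboles sweep dose_a linearly over [0, (D_x)_a] and solve dose_b per
point by bisection (effect matched within 0.1 percentage points). The
optimal combination minimises CI along the sweep parameter by a 33-point
scan refined with bounded golden-section search. CI variation below 1e-5
along an isobole is classified as a flat landscape (that threshold sits
above the 1e-6 dose-inversion noise floor and far below any genuine
synergy signal); sham self-combinations trigger it.

## Packaged network

The LPS→PGE2 pathway (30 nodes, 38 edges) is transcribed from the
TLR4/NF-κB signalling literature: LPS and CD14 form the recognition
complex presented to TLR4; MyD88-dependent (IRAK4→IRAK1→TRAF6) and
TRIF-dependent (TRAF6:RIP1, TRAF3→IRF-5) branches converge on TAK1,
which drives IKK/NF-κB and the three MAP-kinase cascades; NF-κB, AP-1,
CREB (via MSK1) and IRF-5 induce COX-2; COX-2 and PGES produce PGE2 from
arachidonic acid. The figure-level source of this topology prints only
the node/edge counts and a prose walk-through, so the exact arrow list is
this package's transcription: all counts, the 14 docking-target nodes and
the prose-mandated motifs are asserted, but numeric values computed on
the fixture are defined relative to this transcription, not claimed to
match any unpublished adjacency. One consequence worth knowing: with all
14 docking targets fully inhibited the fixture's NEF saturates near 80 %,
not 100 %, because the 24 edges not leaving a target keep resistance 1.

## Synthetic data

`random_pathway` builds layered DAGs — every node gets one forward edge
(guaranteeing a path to the single exit), then random forward shortcuts
densify the graph — because directional flow into an exit is what makes
NF meaningful; Erdős–Rényi graphs are not used. `random_affinities`
draws 1..n_targets records per compound with pKi uniform in a range
(default 5–7, i.e. K_I 0.1–10 μM) over nodes that have outgoing edges.
`synthetic_docking_table` emulates a docking campaign: every compound
scored against every listed target, pKi uniform in [4, 5.5] (K_I ≈ 3–100
μM, the weak-to-moderate range typical of natural-product inhibitors).
All generators are deterministic under their seed, by contract.

What the synthetic data does *not* emulate: correlated affinities across
related targets, docking-score error structure, experimental noise in
inhibition readouts, and incomplete pathway annotation. Passing tests
therefore demonstrate internal consistency of the model and engine, not
predictive accuracy on new biology.

## Problem sizes and tolerances

Test and acceptance runs use networks of ≤ 30 nodes, 12-point curves,
200 random graphs for the brute-force cross-check and 20 random systems
for the Loewe check — sizes at which every check runs in seconds while
still exercising all code paths. Path-length comparisons use absolute
tolerance 1e-9; ties between equal-length paths are irrelevant because
only the length enters the measures.

## Known limitations

* Only non-competitive inhibition; no competitive/uncompetitive variants.
* Only Chou's CI; no Bliss, HSA or ZIP synergy scores, and no ≥3-drug
  combination search (evaluation generalises, the search does not).
* Docking/affinity prediction is out of scope — pKi tables are inputs.
* The claim that maximal synergism occurs at the EC50 dose ratio is
  reported as a diagnostic (`OptimalCombination.ec50_ratio`), not
  asserted: it depends on the affinity table in use.
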