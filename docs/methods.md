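# Methods

`fibrolysis` simulates tPA-initiated degradation of a fibrin clot on two
coupled scales: exact stochastic chemistry on a single fiber cross-section,
and particle transport with distribution-driven fiber failure on a 3D clot
lattice.  This note records the model, the parameters that matter, the
choices made where the model description was genuinely open, and what the
synthetic conditions do and do not establish.

## Microscale: one tPA on one fiber cross-section

A fiber of diameter `d` is represented by the square of equal area
(side `sqrt(pi) d/2`), tiled at the protofibril center-to-center pitch
(9.51 nm at the defaults: 20% protein, 4.8 nm protofibrils on a square
lattice) into an `n x n` grid of binding locations — 9x9 for a 97.5 nm
fiber, 18x18 for 195 nm.  Each location carries 6 binding doublets (paired
binding sites that can simultaneously hold one tPA, one plasminogen and one
plasmin); one doublet per location starts exposed, five cryptic.

A run starts with a single tPA on a uniformly random perimeter location and
evolves by the exact Gillespie algorithm over eight reaction classes:
plasminogen binding (intact 0.1, nicked 1.72 uM^-1 s^-1, at 2 uM) to
accessible exposed doublets; plasminogen unbinding (3.8 s^-1); tPA unbinding
(0.0036 s^-1, or 0.0002 s^-1 while a plasminogen shares its doublet);
activation of any plasminogen at the tPA's location (0.1 s^-1 per pair);
cryptic-site exposure (5 s^-1 per plasmin-cryptic pair at a location);
degradation (5 s^-1 per plasmin-doublet pair at a location); plasmin
crawling (57.6 s^-1); and plasmin unbinding (0.05 s^-1, the molecule is then
instantly inhibited by alpha2-antiplasmin).  Solution-phase plasminogen
reaches only *accessible* locations — the perimeter, plus neighbors of
severed locations — because the 4.8 nm inter-protofibril gap excludes a
9–11 nm macromolecule.  Plasmin, created in place, moves only by crawling.

Several details of this scheme are not pinned down by the published
description; the package resolves them as follows, and these choices were
validated against the published baseline and perturbed-scenario tallies:

* a plasmin does not degrade the doublet its own limbs occupy; any other
  non-degraded doublet at its location (exposed or cryptic) is a target;
* a plasmin whose doublet is degraded by another plasmin immediately rebinds
  a nearby doublet under the crawl-target rule (degradation produces the
  C-terminal lysines it binds), and is lost only if no target exists;
* crawl targets include cryptic doublets, which are exposed on landing —
  the enzyme opens its own path as it works;
* a location is *severed* once at least one of its doublets is degraded
  (`MicroRules.cut_threshold`, default 1), and the cross-section is lysed
  when severed locations form an 8-connected band spanning the grid;
* the run continues to chemical exhaustion (tPA gone and no plasmin left)
  rather than stopping at transection, so every non-censored run ends with
  a kinetic or a forced (plasmin-mediated) tPA departure.

Runs are censored at `t_max` (default 12 h) if the tPA is still bound;
censored runs are counted separately and excluded from distributions.
Determinism: a run is a pure function of (parameters, diameter, seed); the
kernel keeps integer per-location counters, recounts them from the raw state
at termination, and the wrappers raise on any mismatch.

Under the baseline parameter set (n = 2000), ~45% of tPA departures are
forced and ~56% of runs create plasmin and lyse the cross-section, against
47.6% and 58.6% in the reference tallies.  A known limitation: in the
plasminogen-scarce perturbation scenarios (binding and unbinding scaled down
2–3 orders of magnitude at fixed Kd) this reconstruction produces a single
plasmin per run more often, and a lone plasmin fails to complete transection
within its lifetime more often than the reference tallies imply, so those
scenario rows under-count lysis by roughly a factor of two.  The baseline
and perturbed-tPA rows, which the acceptance checks target, are unaffected.

A related consequence of the spare-own rule: the forced-unbind fraction
grows with `k_deg` only while degradation is rate-limiting (up to roughly
`k_deg ~ 2 s^-1`); far above baseline it falls again, because degradation
consumes the cryptic doublets at the tPA's location before they can be
exposed, leaving no doublet from which a plasmin could attack the tPA's own.

## Coupling: empirical distribution packs

A microscale ensemble is compiled into a pack holding the raw tPA residence
times, the forced-unbind probability, the single-fiber lysis probability,
and the lysis delays of lysed runs.  Sampling is inverse-CDF on the raw
samples; no parametric form is imposed.  Residence and delay are drawn
independently per macroscale binding event; the within-run correlation
between the two is a declared approximation isolated behind this interface.

## Macroscale: clot lattice under a bolus

The clot is a cubic lattice with node spacing equal to the pore size — one
periodic slab, one pore deep, width 100 um (50 um in the reduced profile) —
whose edges below the clot surface are fibrin fibers.  Fine clots:
97.5 nm fibers, 1.37 um pores; coarse clots: 195 nm fibers, 2.74 um pores
(same total protein).  A bolus of `round(0.6022 C_nM x width x depth x H)`
discrete tPA molecules starts uniformly in the fibrin-free region of height
`H` and walks the lattice with time step `dt = pore^2/(6 D)`.

* Diffusion: `D = 25 um^2/s` by default — an effective, hindered value for
  tPA in a fibrin network (free-solution tPA is ~50 um^2/s; tortuosity
  roughly halves it).  The scaled-down baseline velocities match the
  reference values with this default and sit ~30% high with the
  free-solution value.
* Binding: a molecule on a node adjacent to a non-degraded fiber binds one
  with probability `1 - exp(-k_on [S] dt)` per step, where `[S]` ~ 4.8 mM is
  the doublet concentration inside the fiber slab itself (6 n^2 doublets per
  22.5 nm of fiber).  Fibrin protein density inside a fiber is
  diameter-independent, so fine and coarse fibers present the same `[S]`.
  This strong-binding regime traps molecules at the clot face, producing
  front-like lysis at baseline; cutting `k_on` by 100x (the small-tPA
  scenario) lets molecules percolate and degrade the clot uniformly.
* Fiber failure: each binding draws a residence time, and with the pack's
  lysis probability a degradation delay; an edge fails at the *minimum* of
  its scheduled delays (each bound tPA attacks its own cross-section along
  the pore-length fiber, and the edge parts at the first transection).
  Released molecules rejoin the free pool with no memory of how they left.

The front depth is the mean over columns of the contiguous fully-degraded
depth from the clot face; front velocity is the least-squares slope of depth
against time from first fiber degradation to full lysis (or the horizon),
in um/min.  A run is front-like if, when half the fibers are gone, at most
20% of degraded fibers lie below the cleared front (both the threshold and
the estimator are configurable; the reference's estimator is unpublished).

## Crawling chain

The two-limb plasmin walker is the three-state CTMC {S11, S10, S00} with
S00 absorbing and no direct S11 -> S00 transition.  The expected number of
steps (S10 -> S11 rebinding events) before absorption is `k_crawl/k_unbind`
= 1152 at the default rates, independent of the S11 -> S10 rate, for which
the package defaults to `2 k_unbind` (two independently releasing limbs);
that rate stretches only the absorption time.  Step counting ignores where
the limb rebinds, so the ratio overestimates the distance processed.

## Synthetic conditions, problem sizes, and what they show

There are no external data: the study conditions are the parameter set above
and the two clot architectures.  Default problem sizes: microscale ensembles
of 1000–2000 runs (the reference used 10,000), macroscale slabs of
50 x 50 um with 3 replicates in the `desk` profile (100 um and 10 replicates
in the `full` profile), and a 5-point ratio sweep on a 25 x 30 um slab.
At these sizes the binomial error on microscale percentages is ~1 point and
scaled-down velocities carry ~10–20% systematic scale effects, which is why
the checks use the tolerances they do.

Two quantitative limitations are known and deliberate:

* the fine/coarse velocity *ratio* at a common bolus runs ~3.3 versus ~2.2
  in the reference, and the fitted fine-coarse crossover lands near
  ~680 molecules/um^2 rather than ~323, because this reconstruction's
  single-fiber delay distribution has a faster lower tail, which the
  minimum-over-draws edge rule amplifies at high tPA counts;
* for the same reason high-ratio fronts advance fast enough that a bolus
  poured as a 49.9 um column lags a concentration-matched thin layer by
  ~15% at feasible domain sizes (the number-equivalence of the two boluses
  is exact in molecule count, and the discrepancy shrinks as the front slows
  or the domain grows); replicate scatter is ~1%, so an equality test at
  two pooled SDs fails even though the two runs are close on the scale of
  the published comparison.
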