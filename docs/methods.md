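# Methods

## Point-charge interference model (`geometry`)

The model reduces the selectivity-filter electrostatics to three formal
charges in a plane: the permeant ion Ca²⁺ (+2e), the domain-III filter
aspartate carboxylate (−1e) and the adjacent lysine ammonium (+1e).
Partial charges, solvation, screening and multi-ion effects are all
deliberately out of model: the point is the *ratio* of the lysine
repulsion to the aspartate attraction, in which the Coulomb constant,
the ion charge and the elementary charge all cancel,

reduction = 100 · (q_K/|q_D|) · a²/r² · cosθ,  r = a·cosθ ± √(b² − a²·sin²θ).

Parameters and defaults:

| symbol | meaning | default | unit |
|---|---|---|---|
| a | ion–aspartate distance | 4.3 (caller-supplied) | Å |
| b | aspartate–lysine distance | 3.8 (caller-supplied) | Å |
| θ | angle at the ion between its directions to aspartate and lysine | 0 | degrees, [0, 90) |
| ϕ | branch selector: angle at the lysine between its directions to ion and aspartate | 0 | degrees, [0, 180] |
| k_e | Coulomb constant | 8.99×10⁹ | N·m²·C⁻² |
| e | elementary charge | 1.60×10⁻¹⁹ | C |

`e` defaults to the two-significant-figure value because the package's
reference forces (2.489×10⁻⁹ N attraction, 0.702×10⁻⁹ N repulsion at the
4.3/3.8 Å geometry) are only reproduced exactly with it; the CODATA
value (1.602176634×10⁻¹⁹ C, giving 2.495×10⁻⁹ N) can be supplied through
`PhysicalConstants`. θ is restricted to [0, 90°) so the axial projection
cosθ stays positive; values outside raise rather than silently flipping
the sign of the "repellent" component.

**The ± branch and ϕ.** Given (a, b, θ), the lysine can sit at either
intersection of the ion's θ-ray with the circle of radius b around the
aspartate. Writing the angle at the *lysine* between its directions to
the ion and to the aspartate as ϕ, the law of cosines gives
cosϕ = (r − a·cosθ)/b = ±√(b² − a²·sin²θ)/b, so ϕ < 90° selects the +
(far) intersection, ϕ > 90° the − (near) one, and ϕ = 90° is exactly the
tangent case r = a·cosθ. This is the only angle convention under which
the three-way branch rule is unconditionally correct — the angle at the
aspartate does not always straddle 90° between the two intersections —
so the package defines ϕ at the lysine and documents it as such. Since
callers often know only which side the lysine is on, ϕ is accepted as a
branch selector by default; `lysine_distance(..., strict_phi=True)`
additionally checks the supplied value against the angle implied by the
embedding and raises on disagreement. The ϕ = 90° case is accepted only
when b = a·sinθ holds to tolerance, because otherwise no planar
placement matches.

Degenerate inputs: b < a·sinθ (ray misses the circle) and r ≤ 0 after
branch evaluation both raise `InfeasibleGeometryError`; sweeps flag such
points per-row instead of aborting.

The net force F_net = F(Ca,D) − F(Ca,K)·cosθ is strictly increasing in r
and crosses zero at r\* = a·√(q_K·cosθ/|q_D|) — with the default charges
and θ = 0, exactly at r = a: a lysine closer to the ion than the
aspartate always reverses the attraction.

## Residue nomenclature and the channel signature (`sequences`)

Residues are addressed as `<domain><segment><position>` with segments
o (S5 outer helix), p (P-loop), i (S6 inner helix). Start positions are
fixed by the alignment convention: helices from 1, P-loops from 33
(window 33–57). The packaged alignment covers α1C and α1G in full
(2 channels × 4 domains × 3 segments); α1H and α1I segments are derived
from the α1G template by the documented point substitutions, with two
footnote entries (position 4o29 on a 27-residue helix) recorded as
uncertain and skipped rather than guessed.

The family call is intentionally minimal: TCC iff residue(3p49) = K and
residue(3p50) ∈ {D, E}; anything else (F or G at 3p49, as in L-type
channels) is LCC. `formal_charge_tally` is a formal-charge bookkeeping
of reduced filter sequences (D/E = −1, K/R = +1, His neutral at pH 7.35)
— a proxy for inspecting charge composition, explicitly *not* an
estimator of solvated boundary-element electrostatic energies, which are
out of scope.

## Selectivity triage (`selectivity`)

Kd = exp(ΔG/RT) with R = 0.001986 kcal·mol⁻¹·K⁻¹ and T = 310 K. The
package also exposes a `printed` convention, Kd = exp(−ΔG/RT), because
the formula circulates typeset with the sign inside the exponential;
evaluated literally with a negative ΔG it produces values above 1
(association-like), so the thermodynamic form — more negative ΔG,
smaller Kd, Kd(0) = 1 M — is the default and every report names the
convention used. The two are exact reciprocals.

Triage rule defaults: T-type receptors α1G/α1H/α1I with target domains
{I, IV}; L-type receptor α1C with target domains {III, IV}; no ΔG
cutoff (any reported pose counts as binding; a threshold is available
for synthetic cohorts). Missing ΔG ("N/A") always means "no predicted
binding" and dominates any printed domain annotation. Where a table's
per-residue label disagrees with its binding-domain column, the domain
column is trusted. Ranking puts TCC-selective compounds first by best
T-type ΔG, breaking ties on higher QED then lower logP; categories and
ranks are invariant under row permutation.

On the packaged panel this rule reproduces the expected calls — the
compound with no α1C pose is TCC-selective, the known cross-blocker is
dual — and also labels one compound (SKF-96365) TCC-selective on the
letter of the rule even though its binding mode is known not to follow
the domain-based mechanism; the tests freeze that output as a regression
snapshot of the rule, not as a pharmacological claim.

## Drug-likeness filter (`properties`)

Descriptors come from the installed RDKit: Crippen–Wildman logP, the
contrib Ertl–Schuffenhauer SA score (1 easy – 10 hard) and Bickerton
QED. Which descriptor parameterisation produced any externally
tabulated value is generally unknowable, so recomputed values carry the
RDKit version and comparisons against printed tables should quote a
tolerance rather than expect bit equality. Structures are scored as
drawn (neutral form); pH-dependent protonation is not applied — a
documented deviation from workflows that protonate at pH 7.35.

The default filter requires a candidate to be strictly below every
reference blocker on logP and strictly above every one on QED; ties
fail. SAS is always reported but not enforced by default: on the
packaged panel the candidates' SAS values (3.1–5.2) sit *above* the
reference blockers' (3.68–3.72), so an "easier to synthesise than every
marketed blocker" criterion would empty the candidate set; a strict
three-criterion mode exists for cohorts where it is meaningful. On the
packaged panel five candidates clear the default filter; the lead
candidate is the passer with both the lowest logP and the highest QED.

## Synthetic cohorts (`synth`)

`generate_cohort` emulates the *shape* of a docking panel — one row per
compound × receptor, N/A entries included — not any docking physics.
Class recipe: TCC-selective compounds bind all three T-type receptors
(domain I or IV, ΔG ~ N(−7.5, 0.5²) kcal/mol) and never α1C; dual
blockers additionally bind α1C (domain III or IV, N(−6.1, 0.4²), T-type
arm N(−7.0, 0.5²)); non-binders are all-N/A. Gaussian draws are
rejection-truncated below zero (favourable energies only; the packaged
panel spans −5.4 to −8.1 kcal/mol, which the defaults bracket). Default
composition is 30% TCC-selective, 20% non-binder, remainder dual.
Properties are class-free uniform draws over logP [3.7, 6.3],
SAS [3.1, 5.2], QED [0.24, 0.64] — the packaged property panel's
candidate extrema; no distributional claim beyond range is intended.
`missingness_noise` drops each present ΔG to N/A independently with the
given probability, emulating docking runs that return no pose.

With zero noise the triage rule recovers every generated label by
construction — that test validates the plumbing, not the rule's power on
real data. What passing synthetic tests does *not* show: robustness to
correlated missingness, to poses in off-target domains, to borderline
energies near a cutoff, or to any structure–energy relationship, none of
which the generator models. A single `numpy` generator seeded from
`CohortSpec.seed` drives all draws; identical specs give byte-identical
CSVs.

Problem sizes used in the shipped tests and acceptance checks: 1000+
random geometry scenes for the triangle-solver oracle, cohorts of
120–400 compounds over 10 seeds for recovery and degradation checks —
sizes at which the binomial standard error (≲1%) is far smaller than the
effects asserted.

## Known limitations

* The Coulomb model is two-dimensional, unscreened and formal-charge
  only; it supports a ranking argument about binding-site preference,
  not energetics in solution.
* The channel-family call rests on a single signature site and the
  packaged alignment's numbering; it is not a general channel
  classifier.
* Docking energies are taken as given; the package neither docks nor
  rescores, and the Kd conversion inherits all of the scoring
  function's error.
* The α1H/α1I derived segments depend on footnote substitution lists
  with two unplaceable entries; residues there are treated as uncertain.
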