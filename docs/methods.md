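# Methods

## Model structure

The package implements a deterministic decision-analytic cost model
comparing a facility's annual locomotor-training expenditure in a
"world without" and a "world with" an overground robotic exoskeleton
(RT-exo). The perspective is the facility as purchaser of technology;
the horizon is one year in 2017 USD with no discounting; clinical
effectiveness is assumed equal across strategies, so the entire result
is a cost comparison at conserved session volume.

A facility's annual session volume is `users_per_year ×
sessions_per_user`. That volume is split across strategies by a
market-share mix; the future world moves sessions from donor strategies
(BWSTT, stationary robotics, overground training) to RT-exo — in the
base case, 10% of all sessions. The net budget impact is future minus
current total cost; negative values are savings.

### Cost equations

Per strategy `s` at facility `f` delivering `n` sessions/year:

* **Equivalent annual device cost**: straight-line,
  `EAC = (device_cost + maintenance_annual × contract_years) / lifespan`.
  Contracts shorter than the lifespan (e.g. a 5-year contract on a
  20-year device) are spread as total contract cost over the lifespan —
  a single annual figure without assuming renewal.
* **Per-session device cost**: `EAC / (capacity × adoption_rate)`.
  The allocation base is the sessions the device actually serves:
  capacity defaults to 2000 sessions/year (8 one-hour slots/day × 250
  operating days) and the adoption rate to 50% (the device sits idle
  half the time), i.e. ≈1000 billable device-sessions/year. Charging
  the full EAC against each strategy's own session count regardless of
  utilization is ruled out by the reported per-strategy cost cells
  (a facility's stationary-robotic annual cost is well below the
  device's full EAC), so allocation per adopted-capacity session is
  the identifying assumption of the cost model.
* **Per-session personnel cost**: Σ heads × hourly wage × duration
  (one hour including set-up, by default). Wages come from the facility
  wage table; a role-level override is supported.
* **Annualized training cost**: `trainees × hours × PT wage / lifespan`.
  Two clinicians per site by default; trainee time is priced at the
  physical therapist wage (the sources do not state whose time is
  costed) and amortized over the device lifespan, since certification
  is device-specific. The charge applies whenever the strategy delivers
  any sessions, in both worlds — donor strategies remain in the future
  portfolio and keep their training cost.

Device and maintenance components of a cost breakdown split the
allocated device cost in proportion to their shares of the EAC, so the
reported components always sum to the total.

### Session accounting

Printed session counts are canonical: when a mix carries explicit
counts they override the rounded percentage shares (the two disagree in
the source tables). Shares must sum to 1 ± 0.005; counts that disagree
with the facility total by more than one session per strategy produce a
warning, not an error, because one study facility ships exactly such an
inconsistency (future counts sum to 3888 against a 3968 total). A
second facility's table prints an annual total of 3105 although its
users × sessions product is 3100; `Facility.annual_sessions` carries
such a canonical total, and the session-volume operation prefers it.
Share-to-count allocation rounds half-up; integer apportionment
(scenario donors, Dirichlet substitution draws, synthetic mixes) uses
largest-remainder so counts always conserve exactly.

`apply_substitution` accepts an explicit recipient session count that
may differ from the donated sum by up to one session per strategy —
needed to represent a published future column whose donors sum to 224
while the printed exoskeleton count is 226.

## Sensitivity analyses

**One-way (tornado)**: RT-exo device cost multiplier 0.5–2.0, RT-exo
adoption rate 0.10–1.00, donor policy {highest-cost, lowest-cost
substituted}, RT-exo device life 3–8 years. Numeric grids use 9 evenly
spaced points with the base value inserted; invalid values (e.g.
adoption 0) are skipped with a warning. When device life varies, the
maintenance contract length tracks the life (maintenance is a running
annual charge on the exoskeleton). Donor policies rank donors by
per-session total cost (personnel + allocated device, excluding the
fixed training charge) and take the exoskeleton's sessions from the
top- or bottom-ranked donor, spilling to the next if it runs dry.

**Scenario shifts**: raise one conventional strategy's share by 10
points of total sessions, donors reduced proportionally to their
current counts via largest-remainder; equivalent to an explicit
substitution vector, and tested to agree with one.

**Probabilistic (PSA)**: per draw, wages are sampled per role (gamma,
mean = base wage, CV 0.2), the RT-exo device cost gets a uniform ±50%
multiplier, and the substitution vector is redrawn from a Dirichlet
over the base donation proportions (concentration 10), apportioned to
integer counts. The published appendix with the study's own families
and variances is not available, so these are the package's defaults —
configurable per run, and chosen to mirror the spans the one-way
analysis uses where a span is stated. Draws are consumed in a fixed
documented order (wages by sorted role name, then the device
multiplier, then substitution weights) from a single seeded generator,
so a given seed and spec reproduce the per-draw sequence bit for bit.
Draws outside the model's domain (a donor asked for more sessions than
it holds) are rejected and redrawn, with the rejection count reported.
Degenerate "point" families reproduce the base case exactly and anchor
the PSA tests.

## Fixtures and what is (not) reproducible

The four packaged facilities carry the reported volumes (2752, 3968,
2256, 3105 sessions/year), strategy cost components, market-share
mixes with printed counts, and the facility-specific BWSTT roster
override (one facility staffs it with 1 PT + 3 exercise specialists).
The study's wage inputs were taken from the Bureau of Labor Statistics
by facility location but never published; the fixtures therefore ship
**placeholder** wage tables (2017 BLS occupational medians, PT ≈
$41–45/hr, exercise specialist ≈ $23–25/hr, aide ≈ $12.5–14/hr),
flagged as uncalibrated. Consequences:

* Reported *absolute* per-strategy cost cells are not reproduction
  targets. They are packaged as reference data, and the two facilities
  whose cells sum to their printed totals exactly serve as aggregation
  identities (savings of $2825 and $2543). The other two facilities'
  cells do not sum to their printed totals and are flagged.
* Everything wage-independent is asserted exactly: session arithmetic,
  allocation counts, substitution accounting, and the aggregation
  identities.
* Wage-dependent behaviour is tested structurally: null substitution ⇒
  zero impact; point-mass PSA ⇒ base case; one-way grid at base ⇒ base
  case; exchange-property agreement with a brute-force enumeration
  oracle; the overground-shift savings sign across a ±30% wage sweep;
  and PSA-mean convergence (3 SE at 10⁴ draws) to the analytic
  expectation under symmetric wage noise, which is exact because cost
  is linear in wages.

## Synthetic data

The generator emulates the structure of the study inputs: 80–260
users/year, 12–26 sessions/user, wages uniform in plausible 2017 US
therapist ranges, Dirichlet market shares over the three conventional
strategies materialized as integer session counts, and a substitution
vector donating 10% of sessions to RT-exo proportionally across
donors. Because it works in count space, generated worlds conserve
sessions exactly and never inherit the share/count inconsistencies of
printed tables. It does not emulate patient-level case mix, capacity
queueing, eligibility differences between devices, or reimbursement —
so passing tests on synthetic facilities validate the accounting and
the substitution arithmetic, not the realism of any particular
facility's cost level.

Analysis scripts use problem sizes chosen to keep each run in seconds:
2000 PSA draws per facility (Monte-Carlo SE ≈ 2% of the spread) and
1000 synthetic facilities for the sign-distribution check.

## Known limitations

* Single-year horizon; no population dynamics, waiting lists or
  capacity queueing.
* Equal effectiveness across strategies is assumed, not modelled.
* The capacity/adoption allocation rule is the package's resolution of
  an under-specified costing step; alternative rules (full annual
  charging, usage-proportional charging) change absolute levels but
  not the wage-independent identities.
* PSA distribution families and variances are package defaults, not
  calibrated to the study's (unpublished) choices; published PSA
  outcome figures are therefore documented but not targeted.
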