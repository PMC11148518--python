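# Methods

## The model of the survey office

The package treats a web-RDS survey as a deterministic machine over a
single time-ordered event log. Time is integer seconds on one reference
clock starting at survey launch; this sidesteps time zones in the
scheduled payment runs and makes every run byte-reproducible. All
entities (phones, IPs, device fingerprints) are opaque synthetic
tokens: the engine models the *logic* of identity checks, not identity
itself.

### Coupon code space

Codes are 5 characters over the 54-character alphabet of upper- and
lower-case letters and digits minus the eight ambiguous glyphs
`0 o O i I L l 1`. The alphabet must be case-sensitive: 62 − 8 = 54 is
the only composition consistent with both the exclusion list and the
code pool of 54⁵ = 459,165,024. Pool arithmetic is exact integer
exponentiation. Validation runs the five checks in a fixed order —
issued, activated, unexpired, not cancelled, not used — and reports the
first failure only, so a multiply-defective code has a deterministic
diagnosis. Codes are compared exactly (no case folding): the alphabet
already removes confusable glyphs, so there is nothing to correct.

The coupon expiry window is a configuration parameter. The registry
default is 14 days; the funnel fixture uses 28 days because the
reference delay distribution contains redemptions later than 14 days,
which implies the survey's own window was longer than that.

### Funnel semantics

A submitted coupon is consumed by the submission: duplicate-phone
rejections count as redemptions (the published accounting nests them
inside the redeemed count). Dispositions follow a fixed precedence,
first match wins: unredeemed → duplicate phone → screening incomplete →
ineligible → consent refused → questionnaire incomplete → fraud →
failed attention filter → valid. Fraud outranks the attention filter
because the filter is only applied within non-fraud completers. A
record with no consent response after eligibility is classified as a
consent refusal (the only non-advancing outcome at that stage). Seeds
enter through a coupon-free portal, are still subject to phone
deduplication, and are tracked separately from the coupon-based
denominators used in funnel percentages (all percentages use issued
coupons as denominator).

Eligibility screening returns only eligible / ineligible / incomplete;
which criterion failed is never part of participant-facing output.
Attention-filter failures lose their interview data in analysis but
keep eligibility, degree, and their recruitment edges, and their
recruits remain enrolled.

### Fraud machinery

Signals are advisory and separate from marking, mirroring an operation
where a dashboard reports suspicious transactions and staff decide.
The `rapid_redemption` threshold defaults to 60 seconds; the reference
operation names the factor but no cutoff, so it is configurable. The
`phone_rental_report` signal is an injected event rather than an
inference, because in practice that scheme is discovered by human
call-backs. Cookie anomalies (a device marked *already used*
re-enrolling) are treated as corroborating only — fraudsters clear
cookies or use private browsing, so the absence of the signal proves
nothing.

`mark_fraud` flags records, cancels all their unredeemed referral
coupons, and is idempotent. Recruits of fraudulent recruiters who
themselves pass all checks are retained: only individually flagged
records are excluded.

The mitigation is an effective-dated change of the interview-payment
delay from 3 minutes to 3 days; requests queued before the cutover
retain the delay in force when queued.

### Payments

Amounts are integer cents (interview 940, referral 160 per completed
recruit, blood draw 1940). Referral payments are computed only after
every coupon the recruiter issued is used, cancelled, or expired, and
are processed exclusively on the daily 02:00 run; interview and
blood-draw payments on a 3-minute tick. One payment per (phone, type)
is enforced at queue time and preserved under any interleaving of
queue/process calls. Denomination uses exact dynamic-programming
change-making with a brute-force minimal-multiset oracle in the tests;
greedy splitting is not minimal for non-canonical denomination sets
(e.g. {4.00, 3.00, 1.00} at 6.00), and DP also detects unrepresentable
amounts. The default denomination set {5.00, 2.00, 1.00, 0.20} is a
configuration choice; real e-money code denominations are not modeled.

## The synthetic-data generators

### Funnel fixture

`generate_funnel_fixture` emits a record-level event log — 35 seeds
(21 initial, 14 added during sampling) plus 6207 issued coupons, 3000
of them redeemed — whose replay through the real engine recovers the
reference accounting: 464 duplicate-phone rejections; 297 incomplete
and 136 ineligible screenings leaving 2103 eligible; 8 consent
refusals; 64 abandoned interviews; 2031 completers of whom 317 recruits
(plus 1 seed) are fraudulent; 99 attention-filter failures among the
1714 non-fraud completers; 1615 valid records; redemption delays of
1441/294/574/445/159/49/36/2 across the eight bins; 2090 mobile and 910
desktop redemptions with mobile browsers 1664 Chrome / 393 Safari / 33
other.

Construction: outcome labels for the 3000 redemption slots are a fixed
multiset, randomly permuted, then repaired so the outstanding-coupon
queue can never run dry (a swap moves a completer label forward if the
running supply would hit zero; with these totals the repair is almost
never exercised, but it makes the generator valid under every seed).
Each slot pops the earliest-issued outstanding coupon; fraudulent slots
prefer coupons issued within the fraud subtree rooted at the fraud
seed, and fraudulent records carry fresh "rented" phone numbers (which
is why deduplication does not stop them), IPs from a small shared pool,
and a shared device fingerprint. Delays are drawn per-bin (uniform
within the bin, the open top bin capped at 21 days) from the exact bin
multiset, so bin counts are conserved for any seed. Coupon arithmetic:
35 seeds × 3 + one administrative re-issue of 3 codes to each of 3
seeds + 2031 completers × 3 = 6207. Exactly one fraud completer
straightlines the nine-item battery; all other completers are nudged
off accidental straightlining. The single phone-rental report event
that drives the audit is emitted after the last fraudulent enrollment.

The fixture reproduces *counts*; published browser percentages are not
reproduced because they are mutually inconsistent with their own counts
under any denominator, and the mobile/desktop narrative percentages
follow from the counts. Wave structure, inter-arrival dynamics, and
geography are schematic (random provinces over 6 regions), so passing
the fixture demonstrates the correctness of the accounting machinery,
not realism of recruitment dynamics.

### Population and simulator

`generate_population` builds a simple undirected contact graph with
configurable degree distribution (constant, Poisson, lognormal; minimum
degree 1), a group attribute with a within-group stub preference *w*
(attribute assortativity increases monotonically in *w*), a binary
trait with known prevalence, and region/province labels. Constant
degree with *w* = 0 uses an exact random regular graph; otherwise edges
are initiated per node with biased partner choice and realized degrees
track the target approximately.

`run_recruitment` is an event-driven loop: completers offer coupons to
up to *k* uniformly chosen not-yet-enrolled neighbors (default *k* = 3,
reducible to 0 for a controlled halt); each offer is redeemed with
probability `redemption_probability` (default 0.48, the observed
redemption fraction) after a delay drawn piecewise-uniformly from the
observed bins. Stage attrition uses the observed conditional rates
(screening incomplete 297/2536, ineligible 136/2536, consent refusal
8/2103, abandonment 64/2095, attention failure 99/1714). Fraud agents
enroll through their own referral codes with fresh rented phones at a
Poisson daily rate that switches to a lower rate at the mitigation day
(default day 33). A neighbor may receive coupons from several
recruiters but can enroll at most once — phone uniqueness enforces
first-come-first-served redemption. Seed addition times default to
evenly spaced over the run.

The simulator emulates funnel structure and chain growth. It does not
model behavioral realism: no diurnal patterns, no degree-dependent
participation, no pandemic-era effects, and fraud agents are
parametric, not adaptive. Tests passing on simulated data therefore
validate the engine's mechanics and estimator behavior under known
conditions, not field performance.

## Analytics choices

- **Estimator.** RDS-II (inverse self-reported degree,
  p̂ = Σ_{i∈A} d_i⁻¹ / Σ_i d_i⁻¹) — the standard default with a closed
  form that is testable (it reduces to the sample proportion under
  constant degree, and recovers a known prevalence in mean under
  degree-proportional-with-replacement sampling; the estimand in those
  checks is the realized finite-population proportion). Degrees are
  taken as recorded; values below 1 are rejected. Variance estimation
  and population-size estimation are out of scope.
- **Waves.** Seeds are wave 0; a recruit's wave is its recruiter's plus
  one. The fraud-excluded analysis view drops flagged nodes but keeps
  ancestry, so retained descendants keep their waves.
- **Convergence.** Operationalized as: the running estimate has stayed
  within ± tolerance (default 0.02) of the final estimate for a window
  of consecutive enrollments (default 100) and never leaves that band
  again; the declared point is the sample size at the end of that first
  window. The underlying notion is verbal ("the estimate stabilizes");
  this is one reasonable sharpening of it.
- **Homophily.** H_a = (observed share of recruiter→recruit pairs with
  an *a* recruiter whose recruit is also *a*) / (RDS-II estimate of the
  population share of *a*). H = 1 is neutral mixing; perfect
  assortativity gives 1/p̂_a. Categories with no recruiting pairs or
  zero estimated share are reported as missing. Other definitions
  (e.g. regression-based) are deliberately out of scope.
- **Delay bins** are half-open `(lo, hi]` with the published edges
  (30 min, 1 h, 6 h, 1 d, 3 d, 7 d, 14 d) and an unbounded top bin, so
  bins partition any positive delay.
- **Device parsing** is a small deterministic classifier over
  user-agent substrings (mobile iff a mobile token is present; browser
  family Chrome before Safari, everything else "other"); it is designed
  for the log's synthetic user agents and common real ones, not as a
  general UA parser. Browser shares are reported within mobile
  redemptions.

## Numerical and degenerate-input behavior

Money never passes through floats (integer cents); pool sizes are exact
integers up to arbitrary length. Token and code generation retry on
collision, so uniqueness is unconditional. Empty logs tabulate to
all-zero tables; empty samples and zero degrees are rejected by the
estimator; a single-node forest has no recruiting pairs and reports all
homophily as missing. Event logs are JSONL with a versioned header;
reading rejects schema mismatches and names the offending line on parse
errors.

## Problem sizes and reproducibility

Default test and acceptance runs use the fixture at its natural size
(6207 coupons, ~23k events, a few seconds to generate), simulator
populations of a few hundred to a few thousand nodes, and 120-replicate
Monte-Carlo checks for estimator recovery; these sizes give exact
count reproduction and stable Monte-Carlo comparisons while keeping the
suite fast. Every stochastic path takes an explicit seed, and all
generated logs record their seed in the metadata header.
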