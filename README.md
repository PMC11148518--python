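# webrds

A desk-scale engine for **web-based respondent-driven sampling (RDS)**
surveys of hidden populations. RDS is a chain-referral design: staff
enroll a handful of *seeds*, each enrolled participant receives a small
number of single-use e-coupons to pass to peers, and inverse-degree
weighting turns the resulting recruitment chains into population-level
estimates. Running RDS on the web replaces the staffed survey office
with software — coupon validation, eligibility screening, consent,
interviewing, peer recruitment, compensation — and creates new failure
modes, chiefly incentive fraud through duplicate enrollment.

`webrds` re-creates that automated office as an importable library for
methodologists and survey engineers: every procedure the web office
performs is an ordinary function operating on an explicit event log, so
funnels, fraud cascades, payment schedules, and RDS diagnostics can be
studied, simulated, and unit-tested without any web infrastructure.

## What is in the box

- **Coupon registry** — 5-character codes over a 54-character
  case-sensitive alphabet (the ambiguous glyphs `0 o O i I L l 1` are
  excluded), giving a pool of 54⁵ = 459,165,024 codes; full attribute
  lifecycle (activated, expiry, cancelled, used) with first-failure
  validation and administrative actions.
- **Enrollment funnel** — portal entry with coupon validation and
  phone-number deduplication, five-criterion eligibility screening,
  consent, 11-digit interview tokens, skip-logic-aware interview
  completion, referral-coupon issuance, and precedence-ordered
  disposition classification.
- **Fraud & quality screening** — rule-based fraud signals (rapid
  redemption, recruiter/recruit shared IP, coupon reuse, device cookie
  anomalies, externally reported phone rentals), an explicit fraud
  marking step whose cascade cancels the flagged records' outstanding
  coupons, the 3-minute→3-day payment-delay mitigation, an
  attention-filter check, and a straightlining scan over nine adjacent
  skip-free items.
- **Payments** — the three compensation types (interview US $9.40,
  peer referral US $1.60 per completed recruit, blood draw US $19.40)
  on their processing schedules (3-minute tick; daily 02:00 referral
  run), one payment per phone per type, and exact minimal-count
  denomination into e-money codes.
- **Recruitment simulator** — agent-based recruitment over a synthetic
  contact network with configurable attrition, redemption delays, and
  fraud agents, emitting the same event-log schema as everything else.
- **Deterministic funnel fixture** — a generated event log of 35 seeds
  and 6207 issued coupons whose replay through the real engine
  reproduces the reference survey's record-level accounting exactly
  (see below).
- **RDS analytics** — recruitment forests and waves, RDS-II
  (Volz–Heckathorn) estimation
  `p̂ = Σ_{i∈A} d_i⁻¹ / Σ_i d_i⁻¹`, convergence traces, homophily
  ratios, and funnel/delay/device/coverage/speed tabulations.

## Worked example

```sh
python examples/02_funnel_fixture.py
```

generates the fixture event log and replays it through the full
pipeline. Output (abridged):

```
Funnel (counts and % of 6207 issued coupons):
                   stage  count  pct_of_issued
                  issued   6207          100.0
              unredeemed   3207           51.7
                redeemed   3000           48.3
         duplicate_phone    464            7.5
                screened   2536           40.9
    screening_incomplete    297            4.8
              ineligible    136            2.2
                eligible   2103           33.9
         consent_refused      8            0.1
               consented   2095           33.8
questionnaire_incomplete     64            1.0
               completed   2031           32.7
                   fraud    317            5.1
     completed_non_fraud   1714           27.6
 failed_attention_filter     99            1.6
                   valid   1615           26.0

fraud enrollments: 318 (1 seed + 317 recruits)
straightlined records: ['P0010'] -> fraud-flagged: [True]
```

Reading it: of 6207 issued e-coupons, 3000 were submitted (redeemed);
464 submissions reused an already-registered phone number and were
rejected; screening, consent, and the interview whittle the remainder
to 2031 completers, of which the audit flags 317 as fraudulent
(enrollments on "rented" phone numbers) and the attention filter
removes another 99, leaving 1615 valid records. Exactly one record
straightlines the nine-item battery, and it belongs to a fraudulent
enrollment.

The other examples walk the coupon lifecycle (`01`), the simulator and
the RDS diagnostics — waves, RDS-II recovery of a known prevalence,
convergence, homophily (`03`), and the payment queue (`04`).

A thin CLI wraps the same functions:

```sh
webrds fixture --out fx.jsonl
webrds analyze fx.jsonl --view delays
webrds audit fx.jsonl
webrds simulate --out sim.jsonl --seed 7
```

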