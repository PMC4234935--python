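# Methods

## The multistate model and its expansion

A *multistate species* is a single conceptual molecule that exists in many
distinguishable forms. It is written as a name with a set of **sites**, each
carrying an **ordered list of states**:

```
Cdh1(p{0:10})                  # integer range, inclusive on both ends: 11 states
S(s1{free,bound,hidden})       # symbolic labels
S(s2{2,4,6,8,0})               # nonconsecutive integers, order as written
Clock(phase{0:3}~circ)         # circular list: the last state connects to the first
```

The order of the list — not the numeric value of the labels — defines the
**successor** and **predecessor** operators: with `s2{2,4,6,8,0}`,
`succ(2) = 4` and `succ(8) = 0`; with `s1{free,bound,hidden}`,
`succ(free) = bound`. On a non-circular list the successor of the last
state (and the predecessor of the first) is undefined, and using it is a
range-coherence error. The language attaches no meaning to state values;
when a state is an integer it may additionally be passed as a number into
kinetic functions.

A *multistate reaction* is one reaction template parameterized over state
ranges:

```
Cdh1(p{0:9}) + ClbM -> Cdh1(succ(p)) + ClbM : MA(kphos)
```

Expansion grounds the template: for every combination of states admitted by
the reactant patterns, one flat single-state reaction is emitted. The rules
are:

- a fixed pattern `p{3}` admits one state; a range `p{0:9}` admits the
  integer states in the inclusive interval (for symbolic lists, the
  positional span between two named labels); a bare mention `p` or an
  unmentioned site admits the full list;
- product states come from fixed patterns, carry-over from the matched
  reactant occurrence (first product of a species pairs with its first
  reactant occurrence, in order), `succ`/`pred` of the matched state, or
  **transfer of state** `site = [succ|pred] Species.site`, which copies the
  (optionally shifted) state of a named reactant;
- a species appearing on both sides with no pattern change carries its
  state through unchanged (sited catalysts work without annotation);
- the number of flat reactions is exactly the product of the admitted
  counts over the constrained sites times the full list lengths of the
  unconstrained ones.

Range bounds may be **variable**: any statically computable expression over
numbers and fixed global quantities (`Cdh1(p{low:high-1})`). Non-integer
values are floored. Rescaling a model — a 20-codon mRNA to 300 codons, a
10-step phosphorylation chain to 4 — is then a single change to one global
quantity followed by re-expansion.

**SUM aggregates** (`SUM(Cdh1; p{1:10}; weight?)`) ground to the explicit
sum of flat instance amounts over the restricted states, each term
multiplied by the weight expression with the site value substituted. A
statically out-of-range restriction is an error; a restriction whose bounds
depend on an enclosing instance's site value (the moving window
`SUM(R; c{M.c+1:M.c+w})`) is instead *clipped* to the state list, because
near the end of a finite chain the window must truncate rather than fail.
The window width here follows the closed-form bound `M.c+1 : M.c+w` with
`w = 14` by default (so 14 terms per full window); `w` is a parameter of
the translation fixture, so a 15-term reading is reproducible by setting
`w = 15`.

**Rate laws.** `MA(k)` produces `k * (product of flat reactant instances)`
per flat reaction. `UD(f(...))` instantiates a user-defined function whose
parameters are role-typed: `GLQ` arguments bind to global quantities or
numbers, `SUB` to the flat instance name of a reactant species, and `SITE`
to the numeric state value of a `species.site` accessor in the current
instance (symbolic states cannot be bound — that is an error). The
distributive-phosphorylation law `dis(GLQ N, SITE i, GLQ k, SUB X, SUB K)
= (N-i)*k*X*K` therefore grounds at instance *i* to the coefficient
`(N-i)*k`, falling as sites fill up, while the ordered mechanism is plain
mass action — switching mechanism changes only the rate-law line.

**Per-instance modifiers.** A modifier written `M(c=R.c)` attaches a
different instance of `M` to each expanded reaction. `M` is declared with
an *open* site (`M(c)`, no state list) and an assignment; each referenced
instance materializes as one flat species carrying one assignment rule with
the instance's site value substituted (`M_c1 = R_c2 + ... + R_c15`, etc.).

**Complexes** are flattened species, not bond graphs: a complex copies the
*tracked* sites of its components (optionally restricted to a subrange) and
optionally generates the complexation/decomplexation reaction pair, which
use transfer-of-state to move each tracked site's value between component
and complex. Auto-generated names join the component names and follow
component renames. Components that are themselves complexes are not
supported (no nesting).

## Diagnostics, editing, and the permissive-model philosophy

Every inconsistency is a diagnostic (`error` / `warning` / `info` with a
stable code and a source location), never an exception: a model with errors
is still a value that can be serialized to `.msl` text and re-read
losslessly. Only expansion refuses to run while error-severity issues are
outstanding. The severity assignment is a documented choice: undefined
references in expressions are errors; auto-created species and empty
expansion ranges are warnings.

Species used in reactions but never defined are resolved by the
autocompletion policy (`silent` create-with-warning / `off` error /
`confirm` pending list), with the default initial amount, the policy
itself, and the default delete policy configurable via a key=value
preferences file.

Deleting an entity resolves each referencing location independently:
`cascade` removes the referencing element (recursively for
expression-bearing entities), `replace_with(v)` substitutes a number into
expressions (and is rejected with an error issue where the reference is a
reaction participant — a number cannot react), `leave_dangling` keeps the
reference and records an error. Renaming (species, globals, functions,
complexes, or a single site via `Species.site`) rewrites every reference,
including SUM aggregates, transfer sources and per-state initial tables,
and is rejected atomically on collision.

## Numerical and representational choices

- Ranges are inclusive at both ends; `{0:10}` has 11 states.
- Identifiers are runs of letters/digits/underscores that are not pure
  numbers; a leading digit is legal (`80S_aatRNA_eEF1A_GTP`).
- The circular flag syntax `~circ` is this implementation's own notation
  (the concept requires a written form; none is standard).
- The document format is sectioned plain text (`species:` / `reactions:` /
  `globals:` / `functions:` / `complexes:` / `initials:`), diffable and
  GUI-free; parse errors are collected per entry so one bad line never
  loses a file.
- Flat names are `base_siteLabel` joined over sites in declaration order
  (`Cdh1_p3`, `X_a0_bfree`); collisions get a deterministic numeric
  suffix plus a warning. Enumeration order is the cartesian product with
  the last site varying fastest. Expansion output is byte-identical across
  runs.
- Per-state initial values override the species default only for the
  listed full state assignments; unlisted states inherit the default.
- An inverted range (`lo > hi`) is an empty state list: a warning and an
  empty expansion, not an error.
- SBML export targets Level 3 Version 1 core: one default compartment of
  size 1 (the language has no compartment concept), species with
  substance-unit amounts, explicit kinetic-law MathML (no SBML-multi
  constructs), assignment rules for SUM-defined quantities and modifier
  instances, and deterministic SId sanitization (underscore prefix for
  names starting with a digit, original names kept in the `name`
  attribute). Documents carry no unit definitions; unit checking is out of
  scope. The in-repo consistency checker verifies SId syntax/uniqueness,
  reference resolution (including every `<ci>` in math), rule-variable
  constraints and MathML arity.

## Fixtures: what they emulate and what they do not

The bundled models are reconstructions of printed worked examples at their
printed sizes: the Cdh1 phosphorylation/dephosphorylation chain (2
collective reactions over `p{0:10}` → 20 flat reactions over 11 forms plus
the kinase), ordered/disordered multisite phosphorylation of XP (one
reaction → N flat reactions, N = 5 by default), the translation-window toy
(default 20 codons, ribosome span d = 3, window w = 14), and a
symbolic/nonconsecutive state demo. Rate constants and initial amounts are
placeholders (1 and 0/1): the originals' full kinetic parameterizations are
not published in reusable form, and no structural count depends on them.
Passing tests therefore demonstrate the *compilation semantics* — counts,
state wiring, rate-law shapes, export validity — not the dynamics of any
published model; the full-scale cell-cycle and translation models (hundreds
of species/reactions) are out of scope because their files are not printed.

## Testing strategy

The expander is checked against an independent brute-force enumerator on
120 randomly generated small models (≤3 sites, ≤5 states each): the oracle
tries every full state combination, filters by pattern membership, and
computes successor/predecessor by integer arithmetic rather than list
order. Operator algebra (pred∘succ identity, circular succ^n identity) is
property-tested with hypothesis (derandomized). Closed-form count laws are
asserted across parameter sweeps (chain length 1..12, N 1..10). All golden
files are byte-compared against their builders, and every fixture's SBML
export must pass the consistency checker with zero errors.

## Known limitations

- No import from SBML/COPASI, no export to COPASI/XPP, no simulation; the
  exported SBML is the hand-off point to simulators.
- No user-defined state-jump operators beyond succ/pred; the progressive
  phosphorylation mechanism is therefore not directly encodable.
- Complexes cannot nest, and bond topology is not tracked.
- SUM weight syntax (`SUM(species; restrictions; weight)`) is this
  implementation's concrete form for a feature whose syntax has no
  published reference.
- Unit declarations are not emitted in SBML.
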