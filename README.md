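# itersurv

Two-player **iterated survival games** with switch-once strategies: exact
payoffs, analytic incentive cutoffs, equilibrium and disequilibrium
stretches, best-response walks, and Monte-Carlo parameter-space surveys.

## The model

Two players play an *n*-step game against Nature. In each step both behave
cooperatively (*C*) or defectively (*D*), and each independently survives
the step with probability

|            | partner C | partner D | alone |
|------------|-----------|-----------|-------|
| **self C** | *a*       | *b*       | *a₀*  |
| **self D** | *c*       | *d*       | *a₀*  |

A player whose partner has died finishes the game alone at the loner rate
*a₀* per step, regardless of strategy. The payoff of a strategy is the
probability of being alive after all *n* steps — payoffs accrue
multiplicatively, which is what makes iterated survival games different from
the classical repeated Prisoner's Dilemma with additive payoffs.

Strategies are restricted to the switch-once family *Sᵢ*: cooperate for the
first *n − i* steps, then defect for the final *i*. Each player's fate is a
three-state absorbing Markov chain over {paired, alone, dead}; the payoff
*A(Sⱼ; Sᵢ)* has a closed form built from the eigenvalues *a²*, *bc*, *d²*
(pair survival per step) and *a₀*.

For a strict single-step Prisoner's Dilemma (*c > a > d > b*, *a² > bc*) the
package computes the cutoffs that organize the incentive structure:

- **a₀\*** — largest *a₀* for which a finite optimal defection count
  *J_opt* against an all-C partner exists,
- **a₀′ / i_D** — one more defection pays iff the partner's defection count
  *i < i_D*; *i_D* exists iff *a₀ < a₀′*,
- **a₀″ / i_C** — one more cooperation pays iff *i > i_C*; exists iff
  *bc > d²* and *a₀ < a₀″*,
- **a₀‴** — where *i_D* and *i_C* cross.

Strategies in ⟦⌈i_D⌉, ⌊i_C⌋⟧ are strict Nash equilibria (local and global
stability coincide); when *i_C < i_D* the interval instead holds
*disequilibria*, from which both defecting more and cooperating more pay,
and best-response walks can end in multi-state cycles.

## Worked example

The running Prisoner's Dilemma (*a, b, c, d* = 0.97, 0.94, 0.99, 0.95 — a
linear transform of the classic 3/0/5/1 payoffs) with *a₀* = 0.86 and
*n* = 20:

```python
>>> import itersurv as iv
>>> g = iv.make_game(0.97, 0.94, 0.99, 0.95, a0=0.86, n=20, require_pd=True)
>>> round(iv.i_C_real(g), 2), round(iv.i_D_real(g), 2)
(4.22, 13.49)
>>> iv.classify_incentives(g).to_dict()["label"]
'5a'
>>> iv.terminal_cycles(g)
{(4, 11)}
```

Because *i_C* = 4.22 sits below *i_D* = 13.49, strategies 5–13 form a
stretch of disequilibria (incentive type 5a): from any of them, defecting
once more *and* cooperating once more both beat standing still. Myopic
best-response play never settles: every walk ends in the two-state cycle
between 4 (= ⌊i_C⌋, the cooperate-side optimum) and 11 defections. The same
game from the shell:

```bash
$ itersurv classify --a 0.97 --b 0.94 --c 0.99 --d 0.95 --a0 0.86 --n 20
$ itersurv walk     --a 0.97 --b 0.94 --c 0.99 --d 0.95 --a0 0.86 --n 20 --start 0
```

Lowering *b* and *c* by 0.01 flips the ordering (*i_D* = 3.08 < *i_C* =
15.99): strategies 4–15 become a stretch of strict equilibria and every walk
converges to one of its endpoints.

A census of the whole parameter space (sorted uniform draws with
*c > a > d > b* and *a² > bc*, *a₀* uniform):

```bash
$ itersurv survey --model full --samples 100000 --seed 1
```

reports that additional defection is favored regardless of the partner's
strategy in about two-thirds of games, stretches of equilibria occupy most
of the rest, and disequilibria are rare — with the median existing *i_C*
around 1.6 defections: the checks on defection sit in the last handful of
steps even in very long games.

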