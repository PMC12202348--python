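# Synthetic two-discipline foundational search matrix with invented terms.
# Shape mirrors a PDICOS-style unified scope: 6 categories x 2 disciplines
# (hms = human movement science, uxg = user experience & game design) x
# 2 perspectives.  Expert cells (row == perspective) and general external-view
# cells use token-disjoint vocabularies so planted corpus labels are
# unambiguous.
name: synthetic-pdicos
disciplines: [hms, uxg]
perspectives: [hms, uxg]
categories:
  - id: population
    label: P
    rows:
      hms:
        hms: [octogenarian, geriatr*, community dwelling]
        uxg: [older adults, seniors]
      uxg:
        uxg: [playtester*, gamer]
        hms: [players, end user]
  - id: design_approach
    label: D
    rows:
      hms:
        hms: [posturograph*, kinesiometric]
        uxg: [movement analysis]
      uxg:
        uxg: [playcentric, ludic design]
        hms: [game concept]
  - id: intervention
    label: I
    rows:
      hms:
        hms: [proprioceptive drills, vestibular regimen]
        uxg: [balance exercises]
      uxg:
        uxg: [exergame*, motion controller]
        hms: [interactive program]
  - id: comparison
    label: C
    rows:
      hms:
        hms: [usual care, waitlist arm]
        uxg: [standard routine]
      uxg:
        uxg: [baseline build, control condition]
        hms: [reference setup]
  - id: outcomes
    label: O
    rows:
      hms:
        hms: [sway amplitude, gait velocity]
        uxg: [mobility]
      uxg:
        uxg: [immersion score, flow rating]
        hms: [enjoyment, engagement]
  - id: study_design
    label: S
    rows:
      hms:
        hms: [randomized trial, crossover protocol]
        uxg: [controlled study]
      uxg:
        uxg: [playtest sessions, heuristic walkthrough]
        hms: [field observation]
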