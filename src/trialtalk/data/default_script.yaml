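# Default session flow: greeting/tutorial -> interview -> confirmation ->
# search -> staged presentation (with dictionary and bookmarking) ->
# refinement -> summary of views -> farewell.  All prompt wording here is
# replacement copy written for this package.
settings:
  wrap_up_after: 150
start: greet
terminals: [farewell]

templates:
  greet: >-
    Hi {name}! I'm Tanya. I can help you look for cancer clinical trials.
    We'll go through it together, one question at a time, and you can
    always change your answers later.
  tutorial_offer: >-
    Before we start searching, would you like me to explain what a
    clinical trial is and how joining one works?
  ask_cancer: >-
    First, what kind of cancer should the trial be about?
  ask_age: >-
    How old is the person the trial is for? Pick the closest age.
  ask_sex: >-
    Is the trial for a woman or a man? Some trials only take one or the
    other.
  ask_location: >-
    Where should the trial be located?
  ask_type: >-
    What kind of trial are you looking for? A treatment trial tests a way
    to treat cancer; other kinds focus on prevention, tests, or support.
  ask_phase: >-
    Do you care which phase the trial is in? Later phases mean the
    treatment has been studied in more people.
  ask_drug: >-
    Some trials use an investigational drug, which is a medicine still
    being studied. Is that OK?
  ask_pain: >-
    Some studies involve procedures that can hurt, like needles or
    biopsies. How much of that is OK with you?
  ask_invasive: >-
    Some studies just ask questions, while others involve tests or
    operations on your body. How much of that is OK?
  ask_burden: >-
    Some studies take a lot of visits and time. How much time are you
    able to give?
  confirm: >-
    Let me make sure I got everything right. Here is what you told me.
    Would you like to change anything?
  search_found: >-
    I searched the trial database and found {n} trials that match what
    you told me. I'll show them to you one at a time, best matches first.
  search_none: >-
    I'm sorry, {name}. I could not find any trials that match everything
    you asked for. We can loosen one of your criteria and try again.
  present_trial: >-
    Here is trial {idx} of {total}: "{title}". Take your time reading;
    I can explain any difficult words.
  dictionary: >-
    Of course. Here is what those medical words mean, in plain language.
  refine: >-
    Here are some ways we could change the search to find more trials.
  summary: >-
    Here are the trials we looked at today. The ones you bookmarked are
    marked with a star.
  farewell: >-
    Thanks for searching with me today, {name}. Your bookmarks are saved
    for next time. Take care!
  basics_what: >-
    A clinical trial is a research study that tests a new way to prevent,
    find, or treat an illness. People join trials by choice, to get new
    treatments early or to help others.
  basics_voluntary: >-
    Joining a trial is always voluntary. You can say no, and you can
    leave a trial at any time, even after it starts. Your regular care
    does not change if you say no.
  basics_risk: >-
    Every trial explains its possible risks and benefits before you
    decide. A person on the study team must go over them with you; that
    conversation is called informed consent.

states:
  greet:
    kind: plain
    template: greet
    choices:
      - label: "Let's get started."
        goto: tutorial_offer
  tutorial_offer:
    kind: plain
    template: tutorial_offer
    choices:
      - label: "Yes, please explain clinical trials first."
        enter: trial_basics
        goto: ask_cancer
      - label: "No thanks, let's start searching."
        goto: ask_cancer
  ask_cancer:
    kind: ask_facet
    facet: cancer_type
    template: ask_cancer
    next: ask_age
  ask_age:
    kind: ask_facet
    facet: age
    template: ask_age
    next: ask_sex
  ask_sex:
    kind: ask_facet
    facet: sex
    template: ask_sex
    next: ask_location
  ask_location:
    kind: ask_facet
    facet: location
    template: ask_location
    next: ask_type
  ask_type:
    kind: ask_facet
    facet: trial_type
    template: ask_type
    next: ask_phase
  ask_phase:
    kind: ask_facet
    facet: phase
    template: ask_phase
    next: ask_drug
  ask_drug:
    kind: ask_facet
    facet: investigational_drug_ok
    template: ask_drug
    next: ask_pain
  ask_pain:
    kind: ask_pref
    criterion: pain
    template: ask_pain
    next: ask_invasive
  ask_invasive:
    kind: ask_pref
    criterion: invasiveness
    template: ask_invasive
    next: ask_burden
  ask_burden:
    kind: ask_pref
    criterion: time_burden
    template: ask_burden
    next: confirm
  confirm:
    kind: confirm
    template: confirm
    accept: search
  search:
    kind: search
    template: search_found
    template_none: search_none
    present: present
    refine: refine
    summary: summary
  present:
    kind: present
    template: present_trial
    dictionary: dictionary
    refine: refine
    summary: summary
    confirm: confirm
  dictionary:
    kind: dictionary
    template: dictionary
    back: present
  refine:
    kind: refine
    template: refine
    search: search
    confirm: confirm
    summary: summary
  summary:
    kind: summary
    template: summary
    done: farewell
  farewell:
    kind: plain
    template: farewell

subnetworks:
  trial_basics:
    start: what
    terminals: [done]
    states:
      what:
        kind: plain
        template: basics_what
        choices:
          - label: "Okay. Is joining a trial required?"
            goto: voluntary
      voluntary:
        kind: plain
        template: basics_voluntary
        choices:
          - label: "Good to know. What about risks?"
            goto: risk
      risk:
        kind: plain
        template: basics_risk
        choices:
          - label: "Got it, thanks."
            goto: done
      done:
        kind: return
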