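# Content-coding framework for within-group chat: six subject areas,
# twenty sub-categories.  Each sub-category links to the collective-action
# factors it is judged to feed ("+") or undermine ("-"):
#   joint_deliberation, negotiate_solutions, utilize_data,
#   monitoring_sanctioning.  off_topic feeds no factor.
version: 1
factors:
  joint_deliberation: "Joint deliberation"
  negotiate_solutions: "Negotiate joint solutions"
  utilize_data: "Utilize social and ecological data"
  monitoring_sanctioning: "Enhance monitoring and sanctioning"
areas:
  topical:
    label: "Topical"
    sub_categories:
      game_understanding:
        label: "Game Understanding"
        factors: {joint_deliberation: "+"}
      past_round:
        label: "Past Round"
        factors: {utilize_data: "+", monitoring_sanctioning: "+"}
      strategy_general:
        label: "General Strategy"
        factors: {joint_deliberation: "+", negotiate_solutions: "+"}
      strategy_specific:
        label: "Specific Strategy"
        factors: {joint_deliberation: "+", utilize_data: "+"}
      off_topic:
        label: "Off-topic Tangents"
        factors: {}
  functional_substantive:
    label: "Functional: Substantive"
    sub_categories:
      information:
        label: "Information"
        factors: {joint_deliberation: "+"}
      suggestion:
        label: "Suggestion"
        factors: {negotiate_solutions: "+"}
      computation:
        label: "Computation"
        factors: {joint_deliberation: "+", utilize_data: "+"}
      elaboration:
        label: "Elaboration"
        factors: {joint_deliberation: "+"}
  functional_maintenance:
    label: "Functional: Maintenance"
    sub_categories:
      positive:
        label: "Positive"
        factors: {joint_deliberation: "+", negotiate_solutions: "+"}
      negative:
        label: "Negative"
        factors: {joint_deliberation: "-", negotiate_solutions: "-"}
      group_learning:
        label: "Procedural/Group Learning"
        factors: {joint_deliberation: "+", negotiate_solutions: "+"}
      subgroup_formation:
        label: "Sub-group Formation"
        factors: {negotiate_solutions: "-"}
  social_ecological_links:
    label: "Social Ecological Links"
    sub_categories:
      awareness:
        label: "Awareness"
        factors: {joint_deliberation: "+", utilize_data: "+"}
      misunderstanding:
        label: "Misunderstanding"
        factors: {joint_deliberation: "-"}
  cpr_group:
    label: "CPR Group"
    sub_categories:
      cpr_identity:
        label: "CPR group identity"
        factors: {negotiate_solutions: "-"}
      cpr_tension:
        label: "Tension caused by CPR (Red/Blue)"
        factors: {negotiate_solutions: "-"}
  harvesting_strategy:
    label: "Harvesting Strategy"
    sub_categories:
      innovation:
        label: "Innovation"
        factors: {joint_deliberation: "+", utilize_data: "+"}
      evolution:
        label: "Evolution"
        factors: {joint_deliberation: "+", utilize_data: "+"}
      revolution:
        label: "Revolution"
        factors: {joint_deliberation: "+", utilize_data: "+"}
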