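# Propositional variables, their once-a-day message categories, and message
# templates.  Placeholders in curly braces are substituted at render time:
#   x  daily step deficit/surplus      x1 weekly step goal / weekly step gap
#   z  sedentary-hour surplus/deficit  m  extra activity minutes today
#   n  activity-minute deficit         n1 weekly activity-minute goal
#   N  current week index              XX, XY indices of the best past weeks
#   X steps today  Y sleep hours  Z sedentary hours  M moderate min  (A-14/15
#   reuse N for vigorous minutes)
# Edit freely; the engine reloads this file via the kb_path argument.
variables:
  - id: A-1
    name: Sedentary
    category: level
    template: "Please continue a light activity (e.g., sports 1-3 days/week, a walking goal of 5000 to 7499 steps/day)"
  - id: A-2
    name: Low_physically_active
    category: level
    template: "Please continue more activity (e.g., sports 3-5 days/week, a walking goal of 7500-9999 steps/day) OR do a minimum 150-300 min (2.5-5.0 h) of moderate-intensity aerobic exercise or minimum 75-150 min of high-intensity aerobic exercise or do an equivalent combination of moderate and high-intensity activities in a week to stay physically active"
  - id: A-3
    name: Physically_active
    category: level
    template: "Please continue the same or more activities based on your goal (e.g., sports 3-5 days/week, a walking goal of 7500 to 9000 steps/ day)"
  - id: A-4
    name: Moderate_physically_active
    category: level
    template: "Please continue the same or more activities based on your goal (e.g., sports 3-5 days/week, a walking goal of 10,000 to 12,499 steps/ day)"
  - id: A-5
    name: Vigorous_physically_active
    category: level
    template: "Please continue the same or more activities based on your goal (e.g., sports 5+ days/week, a walking goal of 12,500+ steps/day)"
  - id: A-6
    name: Sedentary_hour_negative
    category: sedentary
    template: "Please be active for {z} h. more as today you were {z} h. more sedentary beyond your goal"
  - id: A-7
    name: Sedentary_hour_positive
    category: sedentary
    template: "You were very active today and {z} hr. less sedentary; therefore, you can take that h. of rest tomorrow"
  - id: A-8
    name: Steps_negative
    category: steps
    template: "Please continue {x} steps more tomorrow to achieve your weekly goal of {x1} steps"
  - id: A-9
    name: Steps_positive
    category: steps
    template: "You have performed extra {x} steps today beyond your goal; therefore, you can do {x} steps less tomorrow or you can carry out the same pace. You are {x1} step behind to achieve your weekly goal (OR) congratulations! You have achieved your weekly target"
  - id: A-10
    name: Activity_minute_negative
    category: activity_minutes
    template: "Please continue more activity of {n} min tomorrow to achieve {n1} min of a weekly goal"
  - id: A-11
    name: Activity_minute_positive
    category: activity_minutes
    template: "You have performed extra {m} minutes of activity today beyond your goal; therefore, you can be {m} mins. of less highly active tomorrow or you can carry out the same pace. You are {n1} mins. behind to achieve your weekly goal (OR) congratulations! You have achieved your weekly target"
  - id: A-12
    name: Step_forecast_trend_postive
    category: forecast_trend
    template: "Based on your weekly step forecast trend in this Week-{N} you can achieve the step goal"
  - id: A-13
    name: Step_forecast_trend_negative
    category: forecast_trend
    template: "Based on your weekly step forecast trend in this Week-{N} you cannot achieve the step goal. On Week-{XX} and Week-{XY} weeks, you were very active. Please try to follow similar activity patterns"
  - id: A-14
    name: Daily_Goal_achieved
    category: daily_goal
    template: "Good work. Please keep it up tomorrow. You are active and completed the goal for today. Overview: You have performed {X} steps today. You slept {Y} h. You were sedentary for {Z} h. You were {M} min medium active. You were {N} min highly active"
  - id: A-15
    name: Daily_Goal_not_achieved
    category: daily_goal
    template: "You must improve to meet the daily goal. Please stay active tomorrow. Overview: You have performed {X} steps today. You slept {Y} h. You were sedentary for {Z} h. You were {M} min medium active. You were {N} minutes highly active"
  - id: A-16
    name: Weekly_performance_deviation_trend_positive
    category: weekly_deviation
    template: "Congratulations! You have maintained a good weekly activity pattern"
  - id: A-17
    name: Weekly_performance_deviation_trend_negative
    category: weekly_deviation
    template: "Your weekly activity pattern must be improved"
  - id: A-18
    name: Weekly_Goal_achieved
    category: weekly_goal
    template: "Good work. Please keep it up next week. You are active and completed the goal for this week"
  - id: A-19
    name: Weekly_Goal_not_achieved
    category: weekly_goal
    template: "You must improve to meet the weekly goal. Please stay active next week and try to overcome the shortcomings of this week. On Week-{XX} and Week-{XY} weeks, you were very active. Please try to follow similar activity patterns"
  # declared for rule completeness; no weather input exists, so they never fire
  - id: W-1
    name: Good_weather
    category: weather
    template: "The weather is good today; a great day for outdoor activity"
  - id: W-2
    name: Bad_weather
    category: weather
    template: "The weather is bad today; consider indoor activity"
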