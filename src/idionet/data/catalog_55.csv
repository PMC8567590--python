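item_id,code,label
1,bodydiss,Body dissatisfaction
2,drivethin,Drive for thinness
3,fowg,Fear of weight gain
4,overvalwtshape,Overvaluation of weight and shape
5,shame,Shame
6,guilt,Guilt
7,worry,Worry
8,depression,Depressed mood
9,gad,Generalized anxiety
10,ptsd,Post-traumatic stress symptoms
11,adhd,Attention-deficit/hyperactivity symptoms
12,fearlosgcntrol,Fear of losing control
13,fearreject,Fear of rejection
14,fearattn,Fear of attracting attention
15,fearmstkes,Fear of making mistakes
16,feelineffectve,Feeling ineffective
17,saa,Social appearance anxiety
18,socialintanx,Social interaction anxiety
19,avoidemo,Avoiding emotions
20,overwhelmemo,Overwhelming emotions
21,eatrules,Eating rules
22,eatanx,Eating anxiety
23,hungeranx,Anxiety about hunger
24,physsenseat,Physical sensations of eating
25,diffeatpublic,Difficulty eating in public
26,binge,Binge eating
27,skipmeal,Skipping meals
28,foodavoid,Food avoidance
29,repthghtfood,Repetitive thoughts about food
30,mealrum,Meal rumination
31,cogrestraint,Cognitive restraint
32,excexercse,Excessive exercise
33,bodycheck,Body checking
34,selfcrit,Self-criticism
35,highstndrds,High standards
36,allornothing,All-or-nothing thinking
37,impulse,Impulsivity
38,compuls,Compulsions
39,iuc,Intolerance of uncertainty
40,ruminate,Rumination
41,postevprocess,Post-event processing
42,diffrelax,Difficulty relaxing
43,sleepdiff,Sleep difficulties
44,interoaware,Interoceptive awareness
45,restrict,Dietary restriction
46,purge,Purging
47,laxuse,Laxative use
48,fasting,Fasting
49,weighself,Self-weighing
50,bodyavoid,Body avoidance
51,fearfood,Fear foods
52,emoeat,Emotional eating
53,stress,Stress
54,lonely,Loneliness
55,irritable,Irritability
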