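table,scenario,plan,predicted,group,pct
T1,wallace,giving_key,1,TBI,46.2
T1,wallace,giving_key,1,control,18.2
T1,wallace,refusing_key,0,TBI,53.8
T1,wallace,refusing_key,0,control,81.8
T1,at_school,revenging,1,TBI,84.6
T1,at_school,revenging,1,control,81.8
T1,at_school,letting_go,0,TBI,15.4
T1,at_school,letting_go,0,control,18.2
T1,difficult_choice,staying,1,TBI,84.6
T1,difficult_choice,staying,1,control,81.8
T1,difficult_choice,leaving,0,TBI,15.4
T1,difficult_choice,leaving,0,control,18.2
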