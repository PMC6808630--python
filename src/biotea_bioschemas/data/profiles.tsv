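profile	entity_type	tier	property
Journal	Periodical	minimum	name
Journal	Periodical	recommended	issn
Journal	Periodical	recommended	publisher
Journal	Periodical	optional	url
Volume	PublicationVolume	minimum	volumeNumber
Volume	PublicationVolume	recommended	isPartOf
Issue	PublicationIssue	minimum	issueNumber
Issue	PublicationIssue	recommended	isPartOf
ScholarlyArticle	ScholarlyArticle	minimum	name
ScholarlyArticle	ScholarlyArticle	minimum	identifier
ScholarlyArticle	ScholarlyArticle	minimum	author
ScholarlyArticle	ScholarlyArticle	minimum	datePublished
ScholarlyArticle	ScholarlyArticle	recommended	description
ScholarlyArticle	ScholarlyArticle	recommended	isPartOf
ScholarlyArticle	ScholarlyArticle	recommended	pageStart
ScholarlyArticle	ScholarlyArticle	recommended	pageEnd
ScholarlyArticle	ScholarlyArticle	recommended	license
ScholarlyArticle	ScholarlyArticle	recommended	citation
ScholarlyArticle	ScholarlyArticle	recommended	about
ScholarlyArticle	ScholarlyArticle	recommended	url
ScholarlyArticle	ScholarlyArticle	optional	keywords
ScholarlyArticle	ScholarlyArticle	optional	sameAs
SemanticAnnotation	DefinedTerm	minimum	name
SemanticAnnotation	DefinedTerm	minimum	sameAs
SemanticAnnotation	DefinedTerm	recommended	inDefinedTermSet
SemanticAnnotation	DefinedTerm	recommended	subjectOf
SemanticAnnotation	DefinedTerm	optional	termCode
SemanticAnnotation	DefinedTerm	optional	biotea:occurrences
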